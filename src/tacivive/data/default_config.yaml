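# Default run configuration: five-medium biorelevant gradient (open-loop
# USP IV), fasted GI physiology, tacrolimus-like illustrative disposition.
mode: dlm

compound:
  Vc: 700.0          # central volume, L (plasma-referenced)
  Vp: 2400.0         # peripheral volume, L
  Q_dist: 150.0      # inter-compartment clearance, L/h
  CLint_3A4: 6000.0  # hepatic intrinsic clearance, L/h
  CLint_3A5: 0.0     # CYP3A5 non-expressor default
  fu_plasma: 0.01
  Q_h: 90.0          # hepatic blood flow, L/h
  Peff: 1.5          # effective permeability, 1e-4 cm/s
  bp_max: 35.0       # blood:plasma ratio at low concentration
  bp_c50: 2.0        # ng/mL
  gut_clint_3a4: 6.0 # enterocyte CYP3A4 rate at unit abundance, 1/h
  gut_clint_3a5: 0.0
  ent_kout: 5.0      # enterocyte-to-portal exit rate, 1/h
  hematocrit: 0.45

formulation:
  label: formulation
  dose: 5.0          # mg
  density: 1.3       # g/mL
  diffusivity: 5.0e-6  # cm^2/s
  radius_um: 10.0    # monodisperse spray-dried ASD default
  hmax: 30.0         # diffusion-layer cap, um
  solubility: {}     # per-medium overrides, mg/mL (defaults from media below)
  dlm_scalars: {}    # per-medium and/or per-region scalars

protocol:
  cell_volume: 20.0  # mL
  media:
    FaSSGF:
      pH: 1.6
      buffer_total: 0.0
      bile_salt: 0.08
      solubility: 0.002
    FaSSIF-V2:
      pH: 6.5
      buffer_total: 19.1
      buffer_pka1: 1.83
      buffer_pka2: 5.99
      bile_salt: 3.0
      solubility: 0.008
    FaSSIF-V2 midgut:
      pH: 6.8
      buffer_total: 19.3
      buffer_pka1: 1.83
      buffer_pka2: 5.99
      bile_salt: 1.5
      solubility: 0.008
    SIF Ileum-V2:
      pH: 7.5
      buffer_total: 52.8
      buffer_pka1: 1.83
      buffer_pka2: 5.99
      bile_salt: 0.8
      solubility: 0.006
    FaSSCoF:
      pH: 7.8
      buffer_total: 75.8
      buffer_pka1: 1.83
      buffer_pka2: 5.99
      bile_salt: 0.0
      solubility: 0.004
  segments:
    - {medium: FaSSGF, start: 0, duration: 30, flow_rate: 8}
    - {medium: FaSSIF-V2, start: 30, duration: 40, flow_rate: 4}
    - {medium: FaSSIF-V2 midgut, start: 70, duration: 80, flow_rate: 4}
    - {medium: SIF Ileum-V2, start: 150, duration: 60, flow_rate: 4}
    - {medium: FaSSCoF, start: 210, duration: 150, flow_rate: 4}
  region_map:
    FaSSGF: [Stomach]
    FaSSIF-V2: [Duodenum]
    FaSSIF-V2 midgut: [Jejunum I, Jejunum II]
    SIF Ileum-V2: [Ileum I, Ileum II, Ileum III, Ileum IV]
    FaSSCoF: [Colon]

physiology:
  regions: null      # null -> fasted defaults derived from the media above

trial:
  n_subjects: 12
  dose: 5.0
  variability_cv:
    CLint_3A4: 0.35
    Vc: 0.25
    Peff: 0.20
    Q_dist: 0.15
  residual_cv: 0.10
  sample_times_h: [0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 5.0, 6.0,
                   8.0, 12.0, 16.0, 24.0, 36.0, 48.0, 72.0, 96.0, 120.0, 144.0]
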