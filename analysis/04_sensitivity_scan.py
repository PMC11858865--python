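#!/usr/bin/env python
"""Resolve the test product's non-estimable distal scalars by sensitivity
analysis.

The fast test product leaves the Ileum (I-IV, shared) and Colon DLM scalars
unidentified in vitro (02).  Here a virtual observed study generated with
ground-truth distal scalars (0.05, 0.5) is compared against the
one-at-a-time grid — Ileum 0.005/0.05/0.5 at Colon 0.5, Colon 0.05/0.5/5.0
at Ileum 0.05 — under matched random streams, and the pair minimizing the
worst-case fold error across AUC, Cmax and Tmax is selected.

Outputs: results/sensitivity_table.csv, results/sensitivity_ranked.csv,
         results/sensitivity_selected.json
"""

import json
import sys
from pathlib import Path

from tacivive.adam import default_regions
from tacivive.dlm import FormulationModel
from tacivive.metrics import summarize_metrics
from tacivive.pbpk import CompoundDisposition
from tacivive.pipeline import read_observed_pk
from tacivive.sensitivity import apply_scalars, scan_scalars, select_scalars
from tacivive.synthetic import StudySpec, gen_virtual_study

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results")
TRUE_DISTAL = (0.05, 0.5)
PROXIMAL = {"Stomach": 2.0, "Duodenum": 2.0, "Jejunum I": 1.5, "Jejunum II": 1.5}

disp = CompoundDisposition()
form = FormulationModel.monodisperse(dose=5.0, label="test")
base = default_regions(scalars_by_region=PROXIMAL)
spec = StudySpec(seed=SEED)

frame, truth = gen_virtual_study(disp, apply_scalars(base, *TRUE_DISTAL), spec,
                                 mode="dlm", form=form)
frame.to_csv(OUT / "observed_sensitivity_study.csv", index=False)
obs = summarize_metrics(read_observed_pk(OUT / "observed_sensitivity_study.csv"))
obs_means = {m: float(obs[m].mean()) for m in ("auc_0_144", "cmax", "tmax")}
print("observed means:", {k: round(v, 2) for k, v in obs_means.items()})

table = scan_scalars(form, base, disp, spec.variability_cv,
                     n=spec.n_subjects, seed=SEED,
                     sample_times_h=spec.sample_times_h,
                     residual_cv=spec.residual_cv)
chosen, ranked = select_scalars(table, obs_means)
table.frame.to_csv(OUT / "sensitivity_table.csv", index=False)
ranked.to_csv(OUT / "sensitivity_ranked.csv", index=False)
(OUT / "sensitivity_selected.json").write_text(json.dumps(
    {"ileum": chosen[0], "colon": chosen[1], "true": TRUE_DISTAL}, indent=2))

print("\nsensitivity grid (study means per cell):")
print(table.frame.round(2).to_string(index=False))
print(f"\nselected (ileum, colon) = {chosen}; generating pair was {TRUE_DISTAL}"
      + ("  -> recovered" if chosen == TRUE_DISTAL else "  -> NOT recovered"))
tmax_trend = table.frame["tmax"][:3].tolist()
print(f"Tmax across ileum 0.005/0.05/0.5: {[round(t,2) for t in tmax_trend]} "
      "(published tables show a decreasing trend; the direction here depends "
      "on regional CYP3A and permeability settings)")
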