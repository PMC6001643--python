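"""Which variable explains the survival variation?

Nested-model comparison of REw: for each variable, the *inclusion* change
(adding it to a minimal age model) and the *exclusion* change (removing it
from the full model), each also expressed as a percentage.  A variable that
adds a lot on inclusion but little on exclusion is correlated with the
others.
"""

import ranksexplained as rx
from ranksexplained import workflow

spec = rx.scenario_s3(n=1500, seed=8)   # strong stage effect, mild age and deprivation
ds = rx.assemble_dataset(spec)

cfg = workflow.RunConfig.model_validate({
    "re": {"mode": "weighted", "tau": 5.0, "window": 20},
    "model": {"baseline_df": 3},
    "compare": {
        "initial_terms": [{"name": "agez"}],
        "full_terms": [{"name": "agez"},
                       {"name": "stage", "transform": "categorical"},
                       {"name": "dep", "transform": "categorical"}],
        "variables": ["stage", "dep"],
    },
})
table = workflow.variable_contributions(cfg, ds, spec.rate_table)

print(f"REw(5y), initial model (age only): {table.attrs['re_initial']:.3f}")
print(f"REw(5y), full model:               {table.attrs['re_full']:.3f}\n")
print(table.round(3).to_string(index=False))
print("\nStage carries most of the explained variation: adding it to the age")
print("model raises REw substantially, and removing it from the full model")
print("loses almost all of the gain; deprivation contributes little.")
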