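#!/usr/bin/env python
"""Desk-scale survey: fold all 245 grid potentials at L=10.

For every potential the full sequence space (2^10 sequences) is folded
over the complete contact-set inventory; per-map summaries (nu, c, median
foldability, graph decomposition counts) and cross-map artifacts (Jaccard
matrices, group-average dendrogram, universally encoded phenotypes) land
in results/survey_L10/. The 18-mer version of this survey is the same
call with L=18; it is a cluster-scale computation and not run here.
"""

import json
from pathlib import Path

from foldmaps.survey import SurveyConfig, audit_survey, run_survey

root = Path(__file__).resolve().parents[1]
out = root / "results" / "survey_L10"
cfg = SurveyConfig(L=10, potentials="grid", replicates=20, seed=1, outdir=str(out))
summary = run_survey(cfg)
audit_survey(out)

cross = json.loads((out / "cross_map.json").read_text())
print(f"{len(summary)} maps folded at L=10 (audit OK)")
print(
    "non-degeneracy nu in [{:.3f}, {:.3f}], encodability c in [{:.3f}, {:.3f}]".format(
        *cross["nu_range"], *cross["c_range"]
    )
)
print(
    "median foldability in [{:.2f}, {:.2f}]".format(*cross["median_foldability_range"])
)
print(f"phenotypes encoded by every potential: {cross['universal_phenotypes']}")
print("\nmost viable maps:")
print(
    summary.sort_values("nu", ascending=False)
    .head(8)[["label", "type", "nu", "c", "median_foldability"]]
    .to_string(index=False)
)
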