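"""Full pipeline on a synthetic AICE-style fixture.

Builds a genome + peak set in which an AP1-like site (TGACTCA) sits near every
peak summit and an IRF-half-site-like motif (TGAAAC) is planted 0 or 4 bp
downstream of it in 60% of peaks, then runs the complete analysis: window
extraction, de novo primary discovery, recentering, secondary scanning,
binomial spacing statistics and the interaction matrix.
"""
import tempfile
from pathlib import Path

import pandas as pd

from spice import PipelineConfig, run_pipeline
from spice.synthetic_data import aice_demo_spec, make_fixture

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    truth = make_fixture(aice_demo_spec(n_peaks=300, rng_seed=11), tmp / "fixture")
    config = PipelineConfig(
        genome=truth.paths["genome"],
        peaks=truth.paths["peaks"],
        motif_db=truth.paths["motif_db"],
        out_dir=str(tmp / "out"),
        top_n=300,
        widths=(7,),          # search one motif width de novo
        n_seeds=3,
        library_id="demo",
    )
    manifest = run_pipeline(config)

    print("stage counts:", manifest.counts)
    preds = pd.read_csv(tmp / "out" / "predictions.tsv", sep="\t")
    print(preds[["rank", "representative", "best_quadrant", "best_gap",
                 "k", "n", "p_adj", "e_value"]].to_string(index=False))
    report = pd.read_csv(tmp / "out" / "spacing_report.tsv", sep="\t")
    print(report[["secondary_id", "quadrant", "gap", "k", "p_adj"]].to_string(index=False))

# The prediction table ranks motif clusters by their best spacing bin: the
# planted secondary wins with its strongest 1 bp bin, while the spacing
# report keeps every significant bin - here both planted gaps (0 and 4 bp)
# surface, the classic dual AICE spacing. Decoy motifs never reach p < 0.01.
# Gaps are edge-to-edge distances from the *discovered* primary footprint,
# so a discovered motif wider than (or reverse-oriented to) the true site
# shifts or mirrors the reported spacing accordingly.
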