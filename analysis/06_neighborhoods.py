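#!/usr/bin/env python
"""Genomic neighborhoods of every soxY locus: flanking-gene categories,
operon-vs-dispersed architecture calls, and synteny conservation between
loci sharing a planted layout.

Writes neighborhoods.tsv and operons.tsv under results/run.
"""

import itertools
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from soxyprof.neighborhood import compare_synteny  # noqa: E402
from soxyprof.pipeline import RunConfig, run_pipeline  # noqa: E402

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "run"


def main():
    res = run_pipeline(RunConfig(seed=SEED, n_genomes=50, outdir=str(OUT)),
                       upto="neighborhood")
    layout_of = res.truth.set_index("gene_id")["layout"].to_dict()
    verdicts = pd.DataFrame(
        [{"layout": layout_of.get(pid, "?"), "operon": op.verdict}
         for pid, op in res.operons.items()])
    print("operon verdict by planted layout:")
    print(verdicts.groupby("layout")["operon"].agg(["sum", "count"])
          .rename(columns={"sum": "operon_true"}).to_string())
    correct = sum(op.verdict == (layout_of[pid] == "sedimenticola_operon")
                  for pid, op in res.operons.items())
    print(f"\narchitecture discrimination: {correct}/{len(res.operons)}")

    # synteny conservation within vs between layouts
    by_layout: dict[str, list] = {}
    for pid, nmap in res.neighborhoods.items():
        by_layout.setdefault(layout_of[pid], []).append(nmap)
    print("\nmean synteny conservation (category LCS):")
    for layout, maps in sorted(by_layout.items()):
        if len(maps) >= 2:
            scores = [compare_synteny(a, b)
                      for a, b in itertools.combinations(maps[:6], 2)]
            print(f"  within {layout:<28s} {np.mean(scores):.2f}")
    cross = [compare_synteny(a, b) for a, b in itertools.islice(
        itertools.product(by_layout.get("s2_adh", []),
                          by_layout.get("s1c_dms", [])), 10)]
    if cross:
        print(f"  between s2_adh / s1c_dms          {np.mean(cross):.2f}")


if __name__ == "__main__":
    main()
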