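#!/usr/bin/env python
"""Regenerate the cohort analyses from user-supplied TCGA-style exports.

Cohort-specific results (per-gene score tables, Markov-neighborhood
p-value tables, patient counts, candidate gene lists) depend on the TCGA
Firehose archives, which this package does not download.  If you have the
corresponding exports on disk — a binary somatic-mutation gene x sample
matrix, expression and promoter-methylation gene x sample matrices, and a
clinical table with sample_id / tumor_status / vital_status / survival_days
columns — this driver runs the full two-stage analysis on them for both
clinical outcomes and writes every artifact (rank table, selected genes,
discretized data, network JSON/DOT, Markov-neighborhood DOT, post-hoc TSV).

Example:

    python scripts/reproduce_tcga.py \\
        --s-matrix LGG_mutations.tsv --e-matrix LGG_expression.tsv \\
        --m-matrix LGG_methylation.tsv --clinical LGG_clinical.tsv \\
        --outdir results/LGG
"""

from __future__ import annotations

import argparse
from pathlib import Path

from mmibn import InputPaths, MMIConfig, PipelineConfig, ScoreConfig, run_pipeline


def main() -> None:
    parser = argparse.ArgumentParser(
        description=__doc__, formatter_class=argparse.RawDescriptionHelpFormatter
    )
    parser.add_argument("--s-matrix", required=True, help="binary mutation matrix (TSV)")
    parser.add_argument("--e-matrix", required=True, help="expression matrix (TSV)")
    parser.add_argument("--m-matrix", required=True, help="methylation matrix (TSV)")
    parser.add_argument("--clinical", required=True,
                        help="clinical table with sample_id/tumor_status/"
                             "vital_status/survival_days")
    parser.add_argument("--outdir", required=True)
    parser.add_argument("--cdf-cutoff", type=float, default=0.995,
                        help="selection quantile (default 0.995)")
    parser.add_argument("--k", type=int, default=15, help="MMI neighbor count")
    parser.add_argument("--mn-radius", type=int, default=1, choices=(1, 2))
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    inputs = InputPaths(args.s_matrix, args.e_matrix, args.m_matrix, args.clinical)
    for outcome in ("tumor_status", "survival2y"):
        cfg = PipelineConfig(
            inputs=inputs,
            outcome=outcome,
            mmi=MMIConfig(k=args.k),
            selection_parameter=args.cdf_cutoff,
            score=ScoreConfig(seed=args.seed),
            mn_radius=args.mn_radius,
            outdir=str(Path(args.outdir) / outcome),
            seed=args.seed,
        )
        artifacts = run_pipeline(cfg)
        print(f"[{outcome}] artifacts:")
        for name, path in artifacts.items():
            print(f"  {name}: {path}")


if __name__ == "__main__":
    main()
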