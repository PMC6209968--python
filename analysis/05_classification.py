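#!/usr/bin/env python
"""Stage 5: leave-one-out NT-vs-HT classification from the stage-3 summaries.

Evaluates the neural network and every baseline on each single synchrony
measure and on the combined feature vector; writes the accuracy table and
the pooled ROC points of the network on all features.
"""

import argparse
from pathlib import Path

import pandas as pd

from ppgabp import PipelineConfig
from ppgabp.connectivity import MEASURE_KEYS, SubjectSummary
from ppgabp.pipeline import CohortResult, classification_table

ROOT = Path(__file__).resolve().parents[1]


def load_summaries(path: Path) -> list[SubjectSummary]:
    df = pd.read_csv(path)
    return [
        SubjectSummary(
            subject_id=str(row["subject_id"]),
            group=str(row["group"]),
            mean_r=float(row["mean_r"]),
            band_max={k: float(row[k]) for k in MEASURE_KEYS},
            n_epochs_used=int(row["n_epochs_used"]),
        )
        for _, row in df.iterrows()
    ]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--summaries", type=Path,
                        default=ROOT / "results" / "subject_summaries.csv")
    parser.add_argument("--results-dir", type=Path, default=ROOT / "results")
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    config = PipelineConfig(seed=args.seed)
    summaries = load_summaries(args.summaries)
    result = CohortResult(
        summaries=summaries,
        amplitude={"r": {}, "n": {}, "rejected": False},
        orders={},
        diagnostics={},
        manifest={},
        config=config,
    )
    accuracy, roc = classification_table(result, seed=args.seed)

    args.results_dir.mkdir(parents=True, exist_ok=True)
    accuracy.to_csv(args.results_dir / "classification.csv", index=False,
                    float_format="%.10g")
    roc.to_csv(args.results_dir / "roc_points.csv", index=False,
               float_format="%.10g")
    print(accuracy.to_string(index=False))


if __name__ == "__main__":
    main()
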