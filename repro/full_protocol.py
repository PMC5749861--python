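"""Corpus-scale cross-validation protocol (requires external data files).

See repro/README.md for how to obtain and format the three inputs. This
script is not exercised by the test-suite; it documents the exact
invocation behind the corpus-scale numbers.
"""

import argparse
import json
from pathlib import Path

from lrsslmda.core_io import load_associations, load_dags, load_similarity
from lrsslmda.evaluation import global_loocv, kfold_cv, local_loocv
from lrsslmda.pipeline import Dataset, PipelineConfig


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--assoc", required=True, help="HMDD pair list (TSV)")
    ap.add_argument("--fs", required=True, help="functional similarity grid (TSV)")
    ap.add_argument("--dags", required=True, help="disease DAG edge list (TSV)")
    ap.add_argument("--scheme", choices=["global-loocv", "local-loocv", "kfold"],
                    required=True)
    ap.add_argument("--repeats", type=int, default=100)
    ap.add_argument("--budget", type=int, default=None,
                    help="subsample LOOCV rounds (smoke runs only)")
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, required=True)
    args = ap.parse_args()

    dataset = Dataset(
        assoc=load_associations(args.assoc),
        fs=load_similarity(args.fs),
        dags=load_dags(args.dags),
    )
    config = PipelineConfig(seed=args.seed)
    if args.scheme == "global-loocv":
        result = global_loocv(dataset, config, budget=args.budget)
    elif args.scheme == "local-loocv":
        result = local_loocv(dataset, config, budget=args.budget)
    else:
        result = kfold_cv(dataset, config, k=5, repeats=args.repeats, seed=args.seed)
    payload = {"scheme": result.scheme, "auc": result.auc,
               "auc_sd": result.auc_sd, "rounds": result.rounds}
    args.out.write_text(json.dumps(payload, indent=2))
    print(payload)


if __name__ == "__main__":
    main()
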