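#!/usr/bin/env python
"""Run the full pipeline on the public healthy-participant recordings.

NOT part of the test suite: it needs a local copy of the public eye-writing
EOG dataset (https://github.com/EyeWriting/EyewritingNumber), which must be
downloaded separately and converted to this package's manifest layout.

Expected layout (prepared by the user, since the upstream repository's file
organisation is not machine-documented):

    <root>/manifest.csv       columns participant,trial,digit,path
    <root>/<recordings>.csv   native CSV format (``rate=<Hz>`` header line +
                              columns left,right,above,below, microvolts),
                              or EDF/BDF files with a layout JSON mapping
                              channel roles to channel names:
    <root>/layout.json        optional, e.g. {"left": "EXG1", ...}

Usage:
    python scripts/reproduce_public_dataset.py --root data/ --out report.json

Reports leave-one-subject-out accuracy for DTW, DTW+SVM, DPW and DPW+SVM in
the per-participant layout of the package's EvalReport.
"""

import argparse
import json
from pathlib import Path

import eyescript as es
from eyescript.classification import TemplateClassifier
from eyescript.templates import template_traces


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--root", type=Path, required=True)
    parser.add_argument("--out", type=Path, required=True)
    parser.add_argument("--theta", type=float, default=120.0,
                        help="wavelet threshold (microvolt scale)")
    parser.add_argument("--holdout", nargs="*", default=[],
                        help="participants excluded from training folds")
    args = parser.parse_args()

    layout = None
    layout_path = args.root / "layout.json"
    if layout_path.exists():
        layout = json.loads(layout_path.read_text())

    index, recordings = es.load_dataset(args.root, args.root / "manifest.csv",
                                        layout)
    cfg = es.PipelineConfig(threshold=args.theta)
    traces, labels, pids, skipped = [], [], [], []
    for (pid, trial, digit), rec in recordings.items():
        try:
            traces.append(es.reconstruct(rec, cfg))
            labels.append(digit)
            pids.append(pid)
        except es.EyescriptError as exc:
            skipped.append({"participant": pid, "trial": trial,
                            "digit": digit, "error": str(exc)})

    ttraces = template_traces(cfg.n_points)
    out = {"n_epochs": len(traces), "skipped": skipped, "methods": {}}
    import numpy as np
    for measure in ("dtw", "dpw"):
        clf = TemplateClassifier(ttraces, measure)
        dissim = np.array([clf.dissimilarities(t) for t in traces])
        for svm in (False, True):
            report = es.loso_evaluate(traces, labels, pids, ttraces, measure,
                                      svm, holdout_group=set(args.holdout),
                                      dissim=dissim)
            key = measure + ("+svm" if svm else "")
            out["methods"][key] = json.loads(report.to_json())
            print(f"{key:8s} overall accuracy: {report.overall_acc:.4f}")

    args.out.write_text(json.dumps(out, indent=2))
    print(f"report -> {args.out}")


if __name__ == "__main__":
    main()
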