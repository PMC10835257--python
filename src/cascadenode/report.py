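"""Result rendering and run manifests.

Results are rendered as one table row per pipeline stage with the median
and quartiles of balanced/general/training accuracy (percent, one decimal)
and the per-class accuracies computed from the summed confusion matrices.
Every run directory carries a manifest (config snapshot, seeds, input
hashes, timings, package version) from which the run can be re-executed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .models import EvalResult


def _fmt(value: float) -> str:
    if np.isnan(value):
        return "-"
    return f"{100 * value:.1f}"


def result_row(stage: str, result: EvalResult) -> dict:
    """One report row: median [Q1; Q3] metrics plus per-class accuracies."""
    row = {"stage": stage}
    for metric, label in (
        ("balanced_acc", "bal_acc"),
        ("general_acc", "gen_acc"),
        ("train_acc", "train_acc"),
    ):
        med, q1, q3 = result.metrics.loc[metric]
        row[f"{label}_%"] = _fmt(med)
        row[f"{label}_iqr"] = f"[{_fmt(q1)}; {_fmt(q3)}]"
    for cls in result.classes:
        acc = result.per_class_acc[cls]
        row[f"{cls}_%"] = _fmt(acc) if not np.isnan(acc) else "-"
    return row


def render_report(results: dict[str, EvalResult], out_dir) -> pd.DataFrame:
    """Write report.csv (plus a readable report.txt) for the given stages.

    ``results`` maps a stage label (e.g. 'P1', 'P2-S1', 'P2-S2',
    'P2-overall') to its EvalResult.  Returns the report table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame([result_row(stage, r) for stage, r in results.items()])
    table.to_csv(out_dir / "report.csv", index=False)
    (out_dir / "report.txt").write_text(table.to_string(index=False) + "\n")
    for stage, r in results.items():
        safe = stage.replace("/", "_")
        r.summed_confusion.to_csv(out_dir / f"confusion_{safe}.csv")
    return table


def eval_to_dict(result: EvalResult) -> dict:
    """JSON-serializable snapshot of an EvalResult (lossless)."""
    return {
        "classes": list(result.classes),
        "metrics": {m: [float(v) for v in result.metrics.loc[m]]
                    for m in result.metrics.index},
        "summed_confusion": result.summed_confusion.to_numpy().tolist(),
        "per_class_acc": {c: (None if np.isnan(v) else float(v))
                          for c, v in result.per_class_acc.items()},
        "repetitions": [
            {
                "seed": r.seed,
                "predictions": r.predictions.to_dict(),
                "confusion": r.conf.to_numpy().tolist(),
                "balanced_acc": r.balanced_acc,
                "general_acc": r.general_acc,
                "train_acc": None if np.isnan(r.train_acc) else r.train_acc,
            }
            for r in result.repetitions
        ],
    }


def eval_from_dict(data: dict) -> EvalResult:
    """Rebuild an EvalResult from its JSON snapshot."""
    from .models import RepetitionResult, aggregate

    classes = data["classes"]
    reps = [
        RepetitionResult(
            seed=r["seed"],
            predictions=pd.Series(r["predictions"]),
            conf=pd.DataFrame(r["confusion"], index=classes, columns=classes),
            balanced_acc=r["balanced_acc"],
            general_acc=r["general_acc"],
            train_acc=float("nan") if r["train_acc"] is None else r["train_acc"],
        )
        for r in data["repetitions"]
    ]
    return aggregate(reps, classes)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Traceability record written next to every result set."""

    config: dict
    seeds: list[int]
    input_hashes: dict[str, str] = field(default_factory=dict)
    stage_timings_s: dict[str, float] = field(default_factory=dict)
    version: str = __version__
    python: str = platform.python_version()

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def read(cls, path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        return cls(**data)
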