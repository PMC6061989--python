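"""End-to-end orchestration: read, normalize, select, finish, evaluate, report."""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from .io import ExpressionMatrix, normalize_rpm_log2, read_expression
from .selector import DEPanelSelector

logger = logging.getLogger(__name__)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_expression(matrix_path, labels_path, input_type: str = "log2rpm") -> ExpressionMatrix:
    """Read a dataset, normalizing counts to log2-RPM when requested.

    With ``input_type="counts"`` the per-sample library size is taken as
    the sample's total count, the standard reads-per-million convention.
    """
    em = read_expression(matrix_path, labels_path)
    if input_type == "counts":
        library_sizes = em.values.sum(axis=1)
        em = ExpressionMatrix(
            values=normalize_rpm_log2(em.values, library_sizes),
            sample_ids=em.sample_ids,
            feature_names=em.feature_names,
            labels=em.labels,
        )
    elif input_type != "log2rpm":
        raise ValueError("input_type must be 'counts' or 'log2rpm'")
    return em


def write_panel_tsv(report, path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tmiRNA\tcount\tprefix_accuracy\n")
        for row in report.to_rows():
            fh.write(
                f"{row['rank']}\t{row['miRNA']}\t{row['count']}\t"
                f"{row['prefix_accuracy']:.6f}\n"
            )


def run_pipeline(
    matrix_path,
    labels_path,
    out_dir,
    input_type: str = "log2rpm",
    selector: DEPanelSelector | None = None,
    **selector_params,
) -> dict:
    """Execute the full pipeline and write all artifacts under ``out_dir``.

    Stages: read -> (normalize) -> encoder choice -> theta DE runs ->
    majority-vote aggregation -> prefix-accuracy finishing -> panel
    metrics -> cluster quality.  Returns the manifest dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()

    em = load_expression(matrix_path, labels_path, input_type=input_type)
    logger.info(
        "pipeline: %d samples x %d features (%d tumor / %d control)",
        em.n_samples, em.n_features, int(em.labels.sum()), int((1 - em.labels).sum()),
    )
    if selector is None:
        selector = DEPanelSelector(**selector_params)
    selector.fit(em.values, em.labels, feature_names=em.feature_names)

    write_panel_tsv(selector.report_, out_dir / "panel.tsv")
    (out_dir / "metrics.json").write_text(
        json.dumps(selector.metrics_.as_dict(), indent=2) + "\n"
    )
    (out_dir / "quality.json").write_text(
        json.dumps(selector.quality_.as_dict(), indent=2) + "\n"
    )
    manifest = {
        "started": started,
        "finished": datetime.now(timezone.utc).isoformat(),
        "inputs": {
            "matrix": {"path": str(matrix_path), "sha256": _sha256(matrix_path)},
            "labels": {"path": str(labels_path), "sha256": _sha256(labels_path)},
            "input_type": input_type,
        },
        "params": selector.get_params(),
        "encoder": selector.selection_log_,
        "runs": [
            {
                "run": i,
                "best_indices": vec.tolist(),
                "best_names": [selector.feature_names_[j - 1] for j in vec],
                "best_fitness": float(selector.run_results_[i].best.fitness),
                "history": selector.fitness_histories_[i],
            }
            for i, vec in enumerate(selector.best_vectors_)
        ],
        "panel": {
            "names": selector.panel_names_,
            "selected_size": selector.report_.selected_size,
            "k": selector.report_.k,
            "prefix_accuracies": selector.prefix_accuracies_,
        },
        "metrics": selector.metrics_.as_dict(),
        "quality": selector.quality_.as_dict(),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
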