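"""End-to-end pipeline: preprocess -> train -> evaluate."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .evaluation import EvalReport, evaluate_scores, score_pairs
from .preprocess import ProcessedCycle, TooFewCyclesError, preprocess_record
from .records import DatasetManifest, read_record
from .training import TrainState, train
from .verifier import ModelConfig

logger = logging.getLogger("pulsetwin")


def preprocess_manifest(manifest: DatasetManifest, config: RunConfig,
                        split: str | None = None) -> tuple[list[ProcessedCycle], dict[str, str]]:
    """Preprocess every record of the manifest (optionally one split).

    Records that fail (too few cycles, unreadable file) are skipped and
    reported in the returned ``{record_id: reason}`` map rather than
    aborting the run.
    """
    entries = manifest.entries if split is None else manifest.split(split)
    cycles: list[ProcessedCycle] = []
    skipped: dict[str, str] = {}
    for e in entries:
        try:
            record = read_record(e.path, config.sampling_rate_hz, e.subject_id, e.record_id)
            cycles.append(preprocess_record(record, config))
        except (TooFewCyclesError, ValueError, OSError) as exc:
            skipped[e.record_id] = str(exc)
            logger.warning("skipping record %s: %s", e.record_id, exc)
    return cycles, skipped


def save_cycles(cycles: list[ProcessedCycle], path) -> None:
    """Persist cycles as a delimited table: subject, record, n_averaged, values."""
    rows = []
    for c in cycles:
        row = {"subject": c.subject_id, "record": c.record_id, "n_averaged": c.n_averaged}
        row.update({f"v{i}": v for i, v in enumerate(c.values)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_cycles(path) -> list[ProcessedCycle]:
    table = pd.read_csv(path, sep="\t", dtype={"subject": str, "record": str},
                        float_precision="round_trip")
    value_cols = [c for c in table.columns if c.startswith("v")]
    value_cols.sort(key=lambda c: int(c[1:]))
    return [
        ProcessedCycle(row[value_cols].to_numpy(dtype=float), int(row["n_averaged"]),
                       str(row["subject"]), str(row["record"]))
        for _, row in table.iterrows()
    ]


def run_pipeline(config: RunConfig, manifest: DatasetManifest,
                 model_config: ModelConfig | None = None,
                 out_dir=None) -> EvalReport:
    """Execute the full verification experiment on one manifest.

    Preprocesses both splits, trains the twin network on the train split,
    scores every test pair exhaustively and returns the evaluation report.
    Fully reproducible given ``config.random_seed``.  When ``out_dir`` is
    given, writes the loss log, checkpoint, score tables and report there.
    """
    for tag in ("train", "test"):
        if len({e.subject_id for e in manifest.split(tag)}) < 2:
            raise ValueError(f"manifest needs >= 2 subjects in the {tag} split")

    train_cycles, skipped_train = preprocess_manifest(manifest, config, "train")
    test_cycles, skipped_test = preprocess_manifest(manifest, config, "test")
    if skipped_train or skipped_test:
        logger.info("skipped %d train / %d test records",
                    len(skipped_train), len(skipped_test))

    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    state = train(train_cycles, config, model_config=model_config,
                  loss_log_path=(out_dir / "loss.tsv") if out_dir else None)
    scores = score_pairs(state.model, test_cycles)
    report = evaluate_scores(scores, threshold=config.decision_threshold)

    if out_dir is not None:
        state.model.save(out_dir / "model.npz")
        config.save(out_dir / "config.yaml")
        np.savetxt(out_dir / "roc.tsv", report.roc_points, delimiter="\t",
                   header="fpr\ttpr", comments="")
        np.savetxt(out_dir / "far_frr.tsv", report.far_frr_curve, delimiter="\t",
                   header="threshold\tfar\tfrr", comments="")
        np.savetxt(out_dir / "histogram.tsv", report.histogram, delimiter="\t",
                   header="bin_left\tgenuine\timpostor", comments="")
        np.savetxt(out_dir / "genuine_scores.tsv", scores.genuine_scores)
        np.savetxt(out_dir / "impostor_scores.tsv", scores.impostor_scores)
        (out_dir / "report.txt").write_text(report.summary_text(), encoding="utf-8")
    return report
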