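"""PTB-XL-style directory adapter: multi-label tasks and fold splits.

Maps the benchmark's layout — a metadata table (``ptbxl_database.csv``),
a statement ontology (``scp_statements.csv``) and WFDB signal files — to
per-record binary label vectors for the four statement tasks (all /
diagnostic / form / rhythm) and the dataset's ten stratified folds
(1–8 train, 9 validation, 10 test).  A generated mini-fixture with the
same layout exercises the path without the real download.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import ecg_io, wfdb_io
from .stats import MultiLabelResult, format_run_summary, macro_auc

#: class counts of the published statement tasks
TASK_CLASS_COUNTS = {"all": 71, "diagnostic": 44, "form": 19, "rhythm": 12}

TRAIN_FOLDS = tuple(range(1, 9))
VAL_FOLD = 9
TEST_FOLD = 10


@dataclass
class StatementTask:
    name: str
    classes: list[str]
    labels: pd.DataFrame      # records x classes, binary

    def __post_init__(self):
        if self.name not in TASK_CLASS_COUNTS:
            raise ValueError(f"unknown task {self.name!r}")


def _task_classes(statements: pd.DataFrame, task: str) -> list[str]:
    if task == "all":
        return sorted(statements.index)
    col = task  # ontology flags its categories in like-named columns
    if col not in statements.columns:
        raise ecg_io.FormatError(f"ontology table lacks a {col!r} column")
    flagged = statements[statements[col].fillna(0).astype(float) == 1.0]
    return sorted(flagged.index)


def load_ptbxl(root, task: str = "all", sampling_rate: int = 500,
               likelihood_threshold: float | None = None):
    """Load records, labels and folds from a PTB-XL-style tree.

    Returns ``(records, task_obj, folds)``.  A statement code counts as
    positive when its likelihood is nonzero (or at least
    ``likelihood_threshold`` when given).  Records with no statement in
    the task keep an all-zero label row.
    """
    root = Path(root)
    meta_path = root / "ptbxl_database.csv"
    scp_path = root / "scp_statements.csv"
    if not meta_path.exists() or not scp_path.exists():
        raise ecg_io.FormatError(
            f"{root} lacks ptbxl_database.csv / scp_statements.csv"
        )
    meta = pd.read_csv(meta_path, index_col="ecg_id")
    statements = pd.read_csv(scp_path, index_col=0)
    classes = _task_classes(statements, task)

    fname_col = "filename_hr" if sampling_rate == 500 else "filename_lr"
    records, label_rows, folds = [], [], []
    for ecg_id, row in meta.iterrows():
        rec = ecg_io.read_wfdb(root / row[fname_col],
                               resample=(sampling_rate != 500))
        rec.record_id = str(ecg_id)
        rec.patient_id = str(row["patient_id"])
        records.append(rec)
        codes = ast.literal_eval(row["scp_codes"])
        labels = np.zeros(len(classes))
        for code, likelihood in codes.items():
            if code not in classes:
                continue
            if likelihood_threshold is None:
                positive = float(likelihood) != 0.0
            else:
                positive = float(likelihood) >= likelihood_threshold
            if positive:
                labels[classes.index(code)] = 1.0
        label_rows.append(labels)
        folds.append(int(row["strat_fold"]))
    label_df = pd.DataFrame(label_rows, columns=classes,
                            index=[r.record_id for r in records])
    task_obj = StatementTask(task, classes, label_df)
    return records, task_obj, pd.Series(folds, index=label_df.index,
                                        name="strat_fold")


def fold_split(folds: pd.Series) -> dict[str, np.ndarray]:
    """Boolean index masks for the 8/1/1 fold convention."""
    values = folds.to_numpy()
    return {
        "train": np.isin(values, TRAIN_FOLDS),
        "val": values == VAL_FOLD,
        "test": values == TEST_FOLD,
    }


def run_benchmark(encoder, records, task: StatementTask, folds: pd.Series,
                  cfg=None, repeats: int = 10, seed: int = 0,
                  head_hidden: int = 128) -> MultiLabelResult:
    """Fine-tune ``repeats`` times with distinct seeds; macro-AUC summary.

    Each repeat deep-copies the encoder, attaches a fresh head, fine-tunes
    on folds 1–8 monitoring fold 9, and evaluates macro-AUC on fold 10.
    The run mean/SD is attached and printable via
    :func:`ecgmae.stats.format_run_summary`.
    """
    from .datasets import patch_stack
    from .model import attach_head
    from .training import FinetuneConfig, finetune

    cfg = cfg or FinetuneConfig()
    split = fold_split(folds)
    stack = patch_stack(records)
    y = task.labels.to_numpy(dtype=np.float64)
    runs = []
    last = None
    for r in range(repeats):
        clf = attach_head(encoder, n_outputs=len(task.classes),
                          hidden=head_hidden, seed=seed + r, copy=True)
        run_cfg = FinetuneConfig(batch_size=cfg.batch_size, lr=cfg.lr,
                                 max_epochs=cfg.max_epochs,
                                 plateau_patience=cfg.plateau_patience,
                                 lr_factor=cfg.lr_factor,
                                 stop_patience=cfg.stop_patience,
                                 seed=seed + r)
        clf, _ = finetune(clf, stack[split["train"]], y[split["train"]],
                          stack[split["val"]], y[split["val"]], run_cfg)
        scores = clf.predict_proba(stack[split["test"]])
        last = macro_auc(scores, y[split["test"]])
        runs.append(last.macro)
    return MultiLabelResult(per_class=last.per_class, macro=float(np.mean(runs)),
                            skipped=last.skipped, run_values=runs)


def summarize_runs(result: MultiLabelResult) -> str:
    values = result.run_values
    if len(values) < 2:
        return f"{values[0]:.3f} (00)" if values else "n/a"
    return format_run_summary(values)


def make_mini_fixture(root, n_records: int = 12, n_classes: int = 3,
                      seed: int = 0) -> pd.DataFrame:
    """Write a tiny synthetic PTB-XL-layout tree; returns ground truth.

    Synthetic in every respect: fabricated statement codes (``SYN0``...),
    synthesised 12-lead signals, folds cycling 1..10.  The returned frame
    is the intended binary label matrix indexed by ecg_id.
    """
    from .synth import SynthConfig, _draw_patient, synth_record

    root = Path(root)
    (root / "records500" / "00000").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    classes = [f"SYN{i}" for i in range(n_classes)]
    scp = pd.DataFrame(
        {
            "description": [f"synthetic statement {c}" for c in classes],
            "diagnostic": [1.0] * n_classes,
            "form": [1.0 if i % 2 == 0 else np.nan for i in range(n_classes)],
            "rhythm": [np.nan] * n_classes,
        },
        index=classes,
    )
    scp.to_csv(root / "scp_statements.csv")

    cfg = SynthConfig(seed=seed)
    meta_rows, truth_rows = [], []
    for i in range(n_records):
        ecg_id = i + 1
        state = _draw_patient(rng, cfg, f"PT{i:04d}")
        rec = synth_record(state, seed=seed + i, record_id=f"{ecg_id:05d}_hr")
        fname = f"records500/00000/{ecg_id:05d}_hr"
        wfdb_io.write_record(root / fname, rec.signal, 500.0,
                             list(ecg_io.LEAD_NAMES))
        labels = (rng.random(n_classes) < 0.4).astype(float)
        codes = {c: 100.0 for c, on in zip(classes, labels) if on}
        meta_rows.append(
            {
                "ecg_id": ecg_id,
                "patient_id": 1000 + i,
                "scp_codes": str(codes),
                "strat_fold": (i % 10) + 1,
                "filename_lr": f"records100/00000/{ecg_id:05d}_lr",
                "filename_hr": fname,
            }
        )
        truth_rows.append(labels)
    pd.DataFrame(meta_rows).set_index("ecg_id").to_csv(root / "ptbxl_database.csv")
    return pd.DataFrame(truth_rows, columns=classes,
                        index=[str(r["ecg_id"]) for r in meta_rows])
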