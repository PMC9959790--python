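"""Classification metrics, volcano statistics, repeated-split error
frequencies and report export.

The volcano table pairs, per analyte, the class fold change (positive-class
mean over negative-class mean) with a two-sample t-test p-value.  Welch's
unequal-variance test is the default (``equal_var=True`` restores the pooled
Student test); no multiple-testing correction is applied by default, with
Benjamini–Hochberg q-values available alongside on request.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .chemometrics import classify, pls_fit, pls_predict, scale_matrix


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int
    positive_label: object = 1

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion(y_true, y_pred, positive_label=1) -> ConfusionMatrix:
    """Cross-tabulate binary true vs predicted labels."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred length mismatch")
    pos = y_true == positive_label
    called = y_pred == positive_label
    return ConfusionMatrix(
        tp=int((pos & called).sum()),
        fn=int((pos & ~called).sum()),
        fp=int((~pos & called).sum()),
        tn=int((~pos & ~called).sum()),
        positive_label=positive_label,
    )


def class_metrics(c: ConfusionMatrix) -> tuple[float, float, float, float]:
    """(sensitivity, specificity, false-negative rate, false-positive rate)."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValueError("both classes must be represented")
    sens = c.tp / (c.tp + c.fn)
    spec = c.tn / (c.tn + c.fp)
    return sens, spec, 1.0 - sens, 1.0 - spec


def volcano(values, labels, equal_var: bool = False, fdr: bool = False) -> pd.DataFrame:
    """Per-analyte fold change (positive/negative class means) and t-test p-value.

    ``significant`` flags p < 0.05; ``extreme_fc`` flags fold change outside
    [0.5, 2].  Analytes whose negative-class mean is zero get an undefined
    (NaN) fold change, excluded from the extreme flag.
    """
    if isinstance(values, pd.DataFrame):
        df = values
    else:
        df = pd.DataFrame(np.asarray(values, dtype=float))
    y = np.asarray(labels).astype(int)
    if len(y) != len(df):
        raise ValueError("labels length mismatch")
    pos_df = df.loc[y == 1]
    neg_df = df.loc[y == 0]
    if len(pos_df) < 2 or len(neg_df) < 2:
        raise ValueError("both classes need at least two samples")
    mean_pos = pos_df.mean(axis=0)
    mean_neg = neg_df.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_neg.to_numpy() > 0, mean_pos.to_numpy() / mean_neg.to_numpy(), np.nan)
    _, p = stats.ttest_ind(pos_df.to_numpy(), neg_df.to_numpy(), axis=0, equal_var=equal_var)
    out = pd.DataFrame(
        {
            "fold_change": fc,
            "p_value": p,
            "significant": p < 0.05,
            "extreme_fc": np.where(np.isnan(fc), False, (fc < 0.5) | (fc > 2.0)),
        },
        index=df.columns,
    )
    if fdr:
        out["q_value"] = _benjamini_hochberg(p)
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def repeat_split_frequency(
    X,
    labels,
    k: int = 10,
    n_train: int = 300,
    n_lv: int = 4,
    threshold: float = 0.4,
    seed: int = 0,
    center: bool = True,
) -> pd.DataFrame:
    """Per-sample FP/FN frequencies over k random train/validation splits.

    Each run draws an unstratified random split of ``n_train`` training
    samples (re-drawn with a warning if a class goes missing from training),
    SD-scales on the training samples, fits PLS-DA with ``n_lv`` latent
    variables and classifies everything at ``threshold``.  Training-set and
    validation-set errors are tallied separately.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(X, pd.DataFrame):
        index = list(X.index)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        index = list(range(Xa.shape[0]))
    y = np.asarray(labels).astype(int)
    n = Xa.shape[0]
    if not 1 <= n_train < n:
        raise ValueError("n_train must leave a nonempty validation set")
    rng = np.random.default_rng(seed)

    cols = ["fp_train", "fn_train", "fp_val", "fn_val", "n_train_runs", "n_val_runs"]
    tally = pd.DataFrame(0, index=index, columns=cols)
    for _ in range(k):
        while True:
            perm = rng.permutation(n)
            train = perm[:n_train]
            if np.unique(y[train]).size == 2:
                break
            warnings.warn("class missing from a training split; resampling")
        in_train = np.zeros(n, dtype=bool)
        in_train[train] = True
        Xs_tr, scaler = scale_matrix(Xa[train], center=False)
        model = pls_fit(Xs_tr, y[train], n_lv=min(n_lv, Xa.shape[1]), center=center)
        pred = classify(pls_predict(model, scaler.transform(Xa)), threshold)
        fp = (y == 0) & (pred == 1)
        fn = (y == 1) & (pred == 0)
        tally.loc[in_train, "fp_train"] += fp[in_train].astype(int)
        tally.loc[in_train, "fn_train"] += fn[in_train].astype(int)
        tally.loc[~in_train, "fp_val"] += fp[~in_train].astype(int)
        tally.loc[~in_train, "fn_val"] += fn[~in_train].astype(int)
        tally.loc[in_train, "n_train_runs"] += 1
        tally.loc[~in_train, "n_val_runs"] += 1
    tally["class_label"] = y
    return tally


# ---------------------------------------------------------------------------
# Report export
# ---------------------------------------------------------------------------


def _confusion_table(name: str, c: ConfusionMatrix) -> str:
    """Counts with row percentages to one decimal place."""
    def row(label, a, b):
        total = a + b
        pa = 100.0 * a / total if total else 0.0
        pb = 100.0 * b / total if total else 0.0
        return f"{label}\t{a} ({pa:.1f}%)\t{b} ({pb:.1f}%)"

    lines = [
        f"# confusion matrix: {name}",
        "true_class\tpredicted_positive\tpredicted_negative",
        row("positive", c.tp, c.fn),
        row("negative", c.fp, c.tn),
    ]
    return "\n".join(lines) + "\n"


def export_report(
    results: dict,
    out_dir: str | Path,
    seed: int | None = None,
    config: dict | None = None,
    make_plots: bool = False,
) -> list[Path]:
    """Write delimited-text report tables plus a provenance manifest.

    Recognised keys in ``results``: ``confusion`` (dict name ->
    ConfusionMatrix), ``roc`` (ROCCurve), ``volcano`` (DataFrame),
    ``frequency`` (DataFrame), ``rm`` (RMResult), ``fp_fn`` (DataFrame).
    Regeneration from identical inputs is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(name: str, text: str):
        path = out_dir / name
        path.write_text(text, encoding="utf-8", newline="\n")
        written.append(path)

    if "confusion" in results:
        chunks = [_confusion_table(k, v) for k, v in sorted(results["confusion"].items())]
        _write("confusion_matrices.tsv", "\n".join(chunks))
    if "roc" in results:
        r = results["roc"]
        df = pd.DataFrame(
            {"threshold": r.thresholds, "sensitivity": r.sensitivity, "specificity": r.specificity}
        )
        _write("roc.tsv", f"# operating_threshold={r.operating_threshold:.6g}\n"
               + df.to_csv(sep="\t", index=False, float_format="%.6g"))
    if "volcano" in results:
        _write("volcano.tsv", results["volcano"].to_csv(sep="\t", float_format="%.6g"))
    if "frequency" in results:
        _write("frequency_distribution.tsv",
               results["frequency"].to_csv(sep="\t", index=False, float_format="%.6g"))
    if "fp_fn" in results:
        _write("fp_fn_frequency.tsv", results["fp_fn"].to_csv(sep="\t"))
    if "rm" in results:
        rm = results["rm"]
        lines = [f"# selected={','.join(map(str, rm.selected))} rmsecv={rm.rmsecv:.6g}"]
        lines.append("start\tpath\tsubset\trmsecv")
        for start, path_i, subset, v in rm.trajectory:
            lines.append(f"{start}\t{path_i}\t{','.join(map(str, subset))}\t{v:.6g}")
        _write("rm_trajectory.tsv", "\n".join(lines) + "\n")

    if make_plots:
        _export_plots(results, out_dir, written)

    cfg_json = json.dumps(config or {}, sort_keys=True)
    manifest = {
        "seed": seed,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "files": sorted(p.name for p in written),
    }
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    written.append(mpath)
    return written


def _export_plots(results: dict, out_dir: Path, written: list[Path]) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if "volcano" in results:
        v = results["volcano"].dropna(subset=["fold_change"])
        fig, ax = plt.subplots(figsize=(6, 5))
        ax.scatter(np.log2(v["fold_change"]), -np.log10(v["p_value"]),
                   c=np.where(v["significant"], "tab:red", "tab:gray"), s=18)
        ax.axhline(-np.log10(0.05), ls="--", c="k", lw=0.8)
        ax.set_xlabel("log2 fold change (positive / negative)")
        ax.set_ylabel("-log10 p (Welch t-test)")
        fig.tight_layout()
        path = out_dir / "volcano.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    if "roc" in results:
        r = results["roc"]
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.plot(1.0 - r.specificity, r.sensitivity)
        ax.plot([0, 1], [0, 1], ls=":", c="gray")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        fig.tight_layout()
        path = out_dir / "roc.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
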