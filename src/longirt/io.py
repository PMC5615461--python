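"""Reading and writing the delimited long format and item-bank files.

Datasets are comma-separated UTF-8 text with a mandatory header
``subject_id,group,time,item_id,response``; times are real numbers (months
in all shipped presets) and responses contiguous integers starting at 0.
Item banks travel as small YAML files mapping item ids to category counts
and (optionally) thresholds.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd
import yaml

from .links import DomainError
from .model import Item, ItemBank, ResponseDataset, REQUIRED_COLUMNS


def read_item_bank(path) -> ItemBank:
    """Read an item bank from YAML: {item_id: {n_categories, thresholds?}}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    items = []
    for item_id, cfg in raw.items():
        ncat = int(cfg["n_categories"])
        thr = cfg.get("thresholds", [0.0] * (ncat - 1))
        items.append(
            Item(
                item_id=str(item_id),
                n_categories=ncat,
                thresholds=tuple(float(t) for t in thr),
                shift=float(cfg.get("shift", 0.0)),
                discrimination=float(cfg.get("discrimination", 1.0)),
            )
        )
    return ItemBank(tuple(items))


def write_item_bank(bank: ItemBank, path) -> None:
    out = {
        it.item_id: {
            "n_categories": it.n_categories,
            "thresholds": list(it.thresholds),
        }
        for it in bank
    }
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)


def _infer_item_bank(df: pd.DataFrame) -> ItemBank:
    """Item bank inferred from observed categories (max response + 1)."""
    items = []
    for item_id, grp in df.groupby("item_id", sort=True):
        ncat = int(grp["response"].max()) + 1
        ncat = max(ncat, 2)
        items.append(
            Item(
                item_id=str(item_id),
                n_categories=ncat,
                thresholds=tuple(0.0 for _ in range(ncat - 1)),
            )
        )
    return ItemBank(tuple(items))


def read_long_format(path, items: Optional[ItemBank] = None) -> ResponseDataset:
    """Read and validate a long-format dataset.

    If no item bank is given, category counts are inferred from the data.
    Validation errors name the offending rows.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"{path}: missing columns {missing}")
    resp = pd.to_numeric(df["response"], errors="coerce")
    bad = df.index[resp.isna() | (resp != resp.round())].tolist()
    if bad:
        raise DomainError(f"{path}: non-integer responses at rows {bad[:5]}")
    df["response"] = resp.astype(int)
    df["time"] = pd.to_numeric(df["time"])
    bank = items if items is not None else _infer_item_bank(df)
    return ResponseDataset(df, bank)


def write_long_format(data: ResponseDataset, path) -> None:
    data.records.to_csv(path, index=False)


def write_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, index=False)


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("subject_id", "time", "score"):
        if col not in df.columns:
            raise DomainError(f"{path}: missing column {col}")
    return df


def write_fit_table(table: pd.DataFrame, path) -> None:
    """Coefficient table (coefficient, estimate, se, p_value) as CSV."""
    table.to_csv(path, index=False, float_format="%.6g")


def emit_probability_plot_data(curves: pd.DataFrame, path,
                               figure_path: Optional[str] = None) -> None:
    """Stacked-band data for category-probability plots.

    Writes one row per (time, group, category) with the probability and the
    upper-tail cut-point; optionally renders a stacked-area figure.
    """
    curves.to_csv(path, index=False, float_format="%.6g")
    if figure_path:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        groups = sorted(curves["group"].unique())
        fig, axes = plt.subplots(1, len(groups), figsize=(5 * len(groups), 4),
                                 squeeze=False)
        for ax, g in zip(axes[0], groups):
            sub = curves[curves["group"] == g]
            piv = sub.pivot(index="time", columns="category", values="prob")
            ax.stackplot(piv.index, piv.T.values,
                         labels=[f"cat {c}" for c in piv.columns])
            ax.set_xlabel("time")
            ax.set_ylabel("probability")
            ax.set_title(f"group {g}")
            ax.legend(loc="upper right", fontsize="small")
        fig.tight_layout()
        fig.savefig(figure_path, dpi=120)
        plt.close(fig)
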