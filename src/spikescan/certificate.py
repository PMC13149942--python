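"""Digital spike certificate: assembly, group comparison and rendering.

A certificate condenses a spike's per-view feature records into two
blocks — frontal (frontal + back views) and lateral (the two side
views) — each carrying 24 features: the 11 quadrangle-model parameters,
7 outline descriptors, and the mean R, G, B of the body and of the awns.
The awn area (c_Sa) is carried alongside each block as an auxiliary
feature.  Blocks built from two views are the arithmetic mean of the
views' features; missing awn features stay missing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DuplicateViewError, ValidationError
from .morphometry import (
    OUTLINE_FEATURE_NAMES,
    QUAD_FEATURE_NAMES,
    OutlineFeatures,
    QuadrangleFeatures,
)

__all__ = [
    "VIEW_LABELS",
    "CERTIFICATE_FEATURES",
    "AUX_FEATURES",
    "ViewRecord",
    "DigitalCertificate",
    "GroupComparison",
    "assemble_certificate",
    "compare_groups",
    "render_models",
]

VIEW_LABELS = ("frontal", "back", "side1", "side2")
_BLOCK_VIEWS = {"frontal": ("frontal", "back"), "lateral": ("side1", "side2")}

#: The 7 outline descriptors of the certificate (awn area excluded).
OUTLINE_BLOCK_FEATURES = tuple(n for n in OUTLINE_FEATURE_NAMES if n != "c_Sa")

#: The 24 certificate features of one block.
CERTIFICATE_FEATURES = (
    QUAD_FEATURE_NAMES
    + OUTLINE_BLOCK_FEATURES
    + ("body_R", "body_G", "body_B", "awn_R", "awn_G", "awn_B")
)

#: Awn area travels with the block but outside the 24-feature contract.
AUX_FEATURES = ("c_Sa",)


@dataclass(frozen=True)
class ViewRecord:
    """Features of one spike photograph (one view)."""

    spike_id: str
    view_label: str
    outline: OutlineFeatures
    quad: QuadrangleFeatures
    body_rgb: tuple[float, float, float]
    awn_rgb: tuple[float, float, float] = (math.nan, math.nan, math.nan)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.view_label not in VIEW_LABELS:
            raise ValidationError(f"unknown view label {self.view_label!r}")

    def features(self) -> dict[str, float]:
        out = self.quad.as_dict()
        out.update(self.outline.as_dict())
        for name, value in zip(("body_R", "body_G", "body_B"), self.body_rgb):
            out[name] = float(value)
        for name, value in zip(("awn_R", "awn_G", "awn_B"), self.awn_rgb):
            out[name] = float(value)
        return out


@dataclass
class DigitalCertificate:
    spike_id: str
    frontal: dict[str, float] | None
    lateral: dict[str, float] | None
    views_used: dict[str, tuple[str, ...]]

    def block(self, name: str) -> dict[str, float] | None:
        if name not in _BLOCK_VIEWS:
            raise ValidationError(f"unknown block {name!r}")
        return getattr(self, name)

    def to_dict(self) -> dict:
        return {
            "spike_id": self.spike_id,
            "frontal": self.frontal,
            "lateral": self.lateral,
            "views_used": {k: list(v) for k, v in self.views_used.items()},
        }


def _mean_block(records: Sequence[ViewRecord]) -> dict[str, float]:
    keys = CERTIFICATE_FEATURES + AUX_FEATURES
    table = {k: [rec.features()[k] for rec in records] for k in keys}
    out = {}
    for k, vals in table.items():
        arr = np.asarray(vals, dtype=float)
        # nanmean over views: a feature is missing only if no view has it
        out[k] = float(np.nanmean(arr)) if not np.isnan(arr).all() else math.nan
    return out


def assemble_certificate(records: Sequence[ViewRecord]) -> DigitalCertificate:
    """Assemble the per-spike certificate from its view records.

    Order of records is irrelevant.  A spike with views from only one
    block yields a certificate with only that block populated.
    """
    records = list(records)
    if not records:
        raise ValidationError("need at least one view record")
    spike_ids = {r.spike_id for r in records}
    if len(spike_ids) != 1:
        raise ValidationError(f"records span multiple spikes: {sorted(spike_ids)}")
    seen: dict[str, ViewRecord] = {}
    for rec in records:
        if rec.view_label in seen:
            raise DuplicateViewError(
                f"duplicate view label {rec.view_label!r} for spike {rec.spike_id}"
            )
        seen[rec.view_label] = rec

    blocks: dict[str, dict[str, float] | None] = {}
    views_used: dict[str, tuple[str, ...]] = {}
    for block_name, labels in _BLOCK_VIEWS.items():
        present = [seen[v] for v in labels if v in seen]
        blocks[block_name] = _mean_block(present) if present else None
        views_used[block_name] = tuple(r.view_label for r in present)
    return DigitalCertificate(
        spike_id=records[0].spike_id,
        frontal=blocks["frontal"],
        lateral=blocks["lateral"],
        views_used=views_used,
    )


@dataclass
class GroupComparison:
    """Per-feature two-sample comparison between certificate groups."""

    block: str
    alpha: float
    method: str
    correction: str
    table: pd.DataFrame  # feature, mean_a, mean_b, n_a, n_b, statistic, pvalue, significant

    def significant_features(self) -> list[str]:
        sig = self.table[self.table["significant"]]
        return list(sig["feature"])


def _two_sample_test(a: np.ndarray, b: np.ndarray, method: str) -> tuple[float, float]:
    scale = max(np.abs(a).max(), np.abs(b).max(), 1.0)
    if np.var(a) <= (1e-12 * scale) ** 2 and np.var(b) <= (1e-12 * scale) ** 2:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0  # no variance, no difference: p = 1 by convention
        return math.inf, 0.0
    import warnings

    with warnings.catch_warnings():
        # near-constant columns trip scipy's catastrophic-cancellation
        # warning; the zero-variance convention above already covers them
        warnings.filterwarnings("ignore", message="Precision loss occurred")
        if method == "welch":
            res = stats.ttest_ind(a, b, equal_var=False)
        elif method == "mannwhitney":
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
        else:
            raise ValidationError(f"unknown test method {method!r}")
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    certs_a: Sequence[DigitalCertificate],
    certs_b: Sequence[DigitalCertificate],
    block: str = "frontal",
    alpha: float = 0.05,
    correction: str = "bh",
    method: str = "welch",
) -> GroupComparison:
    """Compare certificate features between two groups of spikes.

    Welch's two-sample t-test per feature by default (Mann-Whitney U as
    an option), with Benjamini-Hochberg correction across the 24 + 1
    features (switchable off with correction="none").
    """
    if correction not in ("bh", "none"):
        raise ValidationError(f"unknown correction {correction!r}")
    if method not in ("welch", "mannwhitney"):
        raise ValidationError(f"unknown test method {method!r}")
    blocks_a = [c.block(block) for c in certs_a if c.block(block) is not None]
    blocks_b = [c.block(block) for c in certs_b if c.block(block) is not None]
    if len(blocks_a) < 3 or len(blocks_b) < 3:
        raise ValidationError(
            "each group needs >= 3 spikes with the requested block "
            f"(got {len(blocks_a)} and {len(blocks_b)})"
        )

    rows = []
    for feat in CERTIFICATE_FEATURES + AUX_FEATURES:
        a = np.array([blk[feat] for blk in blocks_a], dtype=float)
        b = np.array([blk[feat] for blk in blocks_b], dtype=float)
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        if len(a) < 3 or len(b) < 3:
            rows.append((feat, math.nan, math.nan, len(a), len(b), math.nan, math.nan))
            continue
        statistic, pvalue = _two_sample_test(a, b, method)
        rows.append(
            (feat, float(a.mean()), float(b.mean()), len(a), len(b), statistic, pvalue)
        )
    table = pd.DataFrame(
        rows,
        columns=["feature", "mean_a", "mean_b", "n_a", "n_b", "statistic", "pvalue"],
    )
    valid = table["pvalue"].notna()
    significant = np.zeros(len(table), dtype=bool)
    if valid.any():
        pvals = table.loc[valid, "pvalue"].to_numpy()
        if correction == "bh":
            reject, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        else:
            reject = pvals < alpha
        significant[np.flatnonzero(valid.to_numpy())] = reject
    table["significant"] = significant
    return GroupComparison(
        block=block,
        alpha=alpha,
        method=method,
        correction=correction,
        table=table,
    )


def _kite_xy(block: dict[str, float]) -> np.ndarray:
    q_l, q_w, q_pw = block["q_L"], block["q_W"], block["q_pW"]
    return np.array(
        [
            [0.0, 0.0],
            [q_w / 2.0, q_pw * q_l],
            [0.0, q_l],
            [-q_w / 2.0, q_pw * q_l],
            [0.0, 0.0],
        ]
    )


def render_models(
    certs: Sequence[DigitalCertificate],
    block: str = "frontal",
    out_path: str | Path | None = None,
    mean_overlay: bool = True,
    ax=None,
    width_magnification: float = 5.0,
):
    """Draw the kite polygon of each certificate, optionally overlaying
    the thick mean-parameter polygon filled with the mean body color.

    The width (X) axis is magnified relative to length (Y) — by a factor
    of 5 by default — to make shape differences visible; both axes are
    in mm.  Returns the matplotlib figure.
    """
    import matplotlib

    if out_path is not None and ax is None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    blocks = [c.block(block) for c in certs if c.block(block) is not None]
    fig = None
    if ax is None:
        fig, ax = plt.subplots(figsize=(3.2, 6.0))
    else:
        fig = ax.figure
    if not blocks:
        import warnings

        warnings.warn("no certificates carry the requested block; nothing drawn")
        return fig

    for blk in blocks:
        xy = _kite_xy(blk)
        ax.plot(xy[:, 0], xy[:, 1], color="tab:blue", linewidth=0.8)

    if mean_overlay:
        mean_blk = {
            k: float(np.nanmean([blk[k] for blk in blocks]))
            for k in ("q_L", "q_W", "q_pW", "body_R", "body_G", "body_B")
        }
        xy = _kite_xy(mean_blk)
        rgb = np.array(
            [mean_blk["body_R"], mean_blk["body_G"], mean_blk["body_B"]]
        )
        fill = tuple(np.clip(rgb / 255.0, 0, 1)) if not np.isnan(rgb).any() else "none"
        ax.fill(xy[:, 0], xy[:, 1], facecolor=fill, edgecolor="red", linewidth=2.5)

    ax.set_aspect(width_magnification)
    ax.set_xlabel("width, mm")
    ax.set_ylabel("length, mm")
    if out_path is not None:
        fig.savefig(out_path, bbox_inches="tight")
        plt.close(fig)
    return fig


def write_certificates(
    certs: Sequence[DigitalCertificate], json_path: str | Path | None = None,
    csv_path: str | Path | None = None,
) -> pd.DataFrame:
    """Serialize certificates as JSON and/or a one-row-per-spike CSV."""
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps([c.to_dict() for c in certs], indent=2)
        )
    rows = []
    for cert in certs:
        row: dict[str, object] = {"spike_id": cert.spike_id}
        for block_name in _BLOCK_VIEWS:
            blk = cert.block(block_name)
            if blk is None:
                continue
            for k, v in blk.items():
                row[f"{block_name}_{k}"] = v
        rows.append(row)
    frame = pd.DataFrame(rows)
    if csv_path is not None:
        frame.to_csv(csv_path, index=False)
    return frame


def load_certificates(json_path: str | Path) -> list[DigitalCertificate]:
    data = json.loads(Path(json_path).read_text())
    certs = []
    for d in data:
        certs.append(
            DigitalCertificate(
                spike_id=d["spike_id"],
                frontal=d["frontal"],
                lateral=d["lateral"],
                views_used={k: tuple(v) for k, v in d["views_used"].items()},
            )
        )
    return certs
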