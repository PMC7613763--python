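"""Study-level aggregation: yields, repeat stability, drug comparisons.

Includes the pulse-train arithmetic (per-cycle period = 2*phase + IPI,
which reproduces the 35 s maximal train), electrode-area geometry, percent
changes, a self-contained Mann-Whitney U test (exact enumeration with
midranks for small samples, tie- and continuity-corrected normal
approximation otherwise), and the drug-report assembly that compares each
feature's post-dose distribution with the last baseline.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ParameterError

__all__ = [
    "PorationProtocol",
    "ComparisonResult",
    "train_duration_s",
    "electrode_area_um2",
    "poration_yield",
    "repeat_summary",
    "percent_change",
    "mann_whitney_u",
    "drug_report",
]

log = logging.getLogger(__name__)

ALPHA = 0.05


@dataclasses.dataclass(frozen=True)
class PorationProtocol:
    """Stimulation pulse-train description.

    A biphasic rectangular pulse contributes two phases of ``phase_us``
    each plus one interpulse interval per cycle.
    """

    vpp_v: float = 1.0
    phase_us: float = 200.0
    ipi_ms: float = 1.0
    n_pulses: int = 25_000
    electrode_ids: Tuple[int, ...] = ()
    selection_strategy: str = "random"
    electrode_area_um2: float = 12.566370614359172

    def __post_init__(self) -> None:
        if not (0.5 <= self.vpp_v <= 2.5):
            raise ParameterError("vpp_v must lie in [0.5, 2.5] V")
        if not (50.0 <= self.phase_us <= 1000.0):
            raise ParameterError("phase_us must lie in [50, 1000] us")
        if self.n_pulses < 0:
            raise ParameterError("n_pulses must be >= 0")
        if self.ipi_ms < 0:
            raise ParameterError("ipi_ms must be >= 0")
        if self.selection_strategy not in ("random", "high_amp"):
            raise ParameterError("selection_strategy must be 'random' or 'high_amp'")
        if self.electrode_area_um2 <= 0:
            raise ParameterError("electrode_area_um2 must be > 0")
        object.__setattr__(self, "electrode_ids", tuple(self.electrode_ids))


@dataclasses.dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one feature comparison (post-dose vs reference)."""

    feature_name: str
    n_pre: int
    n_post: int
    mean_pct_change: float
    sd_pct_change: float
    u_statistic: float
    p_value: float
    significant: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ParameterError("p_value must lie in [0, 1]")
        if self.significant != (self.p_value < ALPHA):
            raise ParameterError("significant flag must equal (p < 0.05)")


def train_duration_s(protocol: PorationProtocol) -> float:
    """Total pulse-train duration: n_pulses * (2*phase + IPI)."""
    return protocol.n_pulses * (2.0 * protocol.phase_us * 1e-6 + protocol.ipi_ms * 1e-3)


def electrode_area_um2(shape: str, **dims: float) -> float:
    """Geometric electrode area in um^2.

    ``electrode_area_um2("circle", diameter_um=4)`` or
    ``electrode_area_um2("rectangle", width_um=5.5, height_um=9.3)``.
    Returns the exact geometric value (a vendor datasheet may print a
    slightly smaller figure for rectangles, presumably due to rounded
    corners).
    """
    if shape == "circle":
        d = dims.get("diameter_um")
        if d is None or d <= 0:
            raise ParameterError("circle requires diameter_um > 0")
        return math.pi * d * d / 4.0
    if shape == "rectangle":
        w, h = dims.get("width_um"), dims.get("height_um")
        if w is None or h is None or w <= 0 or h <= 0:
            raise ParameterError("rectangle requires width_um > 0 and height_um > 0")
        return w * h
    raise ParameterError(f"unknown electrode shape {shape!r}")


def percent_change(pre: float, post: float) -> float:
    """Relative change 100*(post - pre)/pre.

    Note the asymmetry: swapping pre and post changes the magnitude, not
    just the sign, because the reference changes.
    """
    if pre == 0:
        raise ParameterError("pre must be nonzero")
    return 100.0 * (post - pre) / pre


def poration_yield(
    features: pd.DataFrame,
    stimulated: pd.DataFrame,
    amp_threshold_mv: float = 1.0,
) -> pd.Series:
    """Electroporation yield (%) per repeat.

    ``features`` follows the canonical feature-table schema; ``stimulated``
    has columns ``electrode_id`` and ``repeat_idx`` listing every electrode
    that received pulses (successful or not). Yield counts stimulated
    electrodes whose representative waveform is intracellular-like with an
    AP amplitude strictly above the threshold. Electrodes that received no
    pulses are ignored; electrode ordering is irrelevant.
    """
    out = {}
    for rep, grp in stimulated.groupby("repeat_idx"):
        stim_ids = set(grp["electrode_id"])
        if not stim_ids:
            continue
        sub = features[
            (features["repeat_idx"] == rep)
            & features["electrode_id"].isin(stim_ids)
            & (features["label"] == "intracellular_like")
            & (features["ap_amplitude_mv"] > amp_threshold_mv)
        ]
        out[rep] = 100.0 * len(sub) / len(stim_ids)
    return pd.Series(out, name="yield_pct").sort_index()


def repeat_summary(features: pd.DataFrame) -> pd.DataFrame:
    """Per-repeat medians and IQRs of the AP/FP features.

    Repeats with no intracellular-like rows produce an all-NA row (with
    ``n = 0``).
    """
    rows = []
    for rep, grp in features.groupby("repeat_idx"):
        ic = grp[grp["label"] == "intracellular_like"]
        row = {"repeat_idx": rep, "n": len(ic)}
        for col in ("apd90_ms", "tdep_ms", "ap_amplitude_mv"):
            vals = ic[col].dropna()
            row[f"{col}_median"] = vals.median() if len(vals) else np.nan
            row[f"{col}_iqr"] = (
                vals.quantile(0.75) - vals.quantile(0.25) if len(vals) else np.nan
            )
        fp = grp["fp_amplitude_uv"].dropna()
        row["fp_amplitude_uv_median"] = fp.median() if len(fp) else np.nan
        row["fp_amplitude_uv_iqr"] = (
            fp.quantile(0.75) - fp.quantile(0.25) if len(fp) else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("repeat_idx").sort_index()


_EXACT_MAX_COMBINATIONS = 20_000


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of x, p).

    Midranks handle ties. For small samples (min(n, m) <= 8 and at most
    ~2e4 group assignments) the two-sided p is computed by exact
    enumeration of the permutation distribution of U, using
    P(|U - nm/2| >= |u - nm/2|). Larger samples use the normal
    approximation with tie correction and a 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise ParameterError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_x = float(np.sum(ranks[:n]) - n * (n + 1) / 2.0)
    mu = n * m / 2.0

    if min(n, m) <= 8 and math.comb(n + m, n) <= _EXACT_MAX_COMBINATIONS:
        obs_dev = abs(u_x - mu)
        count = 0
        total = 0
        for combo in itertools.combinations(range(n + m), n):
            u = ranks[list(combo)].sum() - n * (n + 1) / 2.0
            if abs(u - mu) >= obs_dev - 1e-9:
                count += 1
            total += 1
        return u_x, count / total

    big_n = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (big_n * (big_n - 1))
    var = n * m / 12.0 * ((big_n + 1) - tie_term)
    if var <= 0:
        return u_x, 1.0
    z = max(abs(u_x - mu) - 0.5, 0.0) / math.sqrt(var)
    p = math.erfc(z / math.sqrt(2.0))
    return u_x, min(p, 1.0)


def drug_report(
    baseline_tables: Mapping[str, pd.DataFrame],
    postdose: pd.DataFrame,
    feature_names: Sequence[str] = ("apd90_ms", "tdep_ms"),
    reference: str = "ctrl3",
) -> Tuple[List[ComparisonResult], pd.DataFrame]:
    """Drug-response report: per-electrode changes vs the last baseline.

    Per-electrode percent changes are computed against the ``reference``
    baseline table (electrodes missing in either phase are dropped with a
    log entry); the test compares the post-dose and reference feature
    distributions across the matched electrodes. Baseline-vs-baseline
    comparisons (ctrl1 vs reference, when present) are appended as a
    stability check; a vehicle arm is handled identically by the caller.
    """
    if reference not in baseline_tables:
        raise ParameterError(f"reference table {reference!r} not provided")
    ref = _intracellular(baseline_tables[reference])
    post = _intracellular(postdose)

    merged = ref.merge(post, on="electrode_id", suffixes=("_pre", "_post"))
    dropped = (set(ref["electrode_id"]) | set(post["electrode_id"])) - set(
        merged["electrode_id"]
    )
    if dropped:
        log.info("drug_report: dropping %d unmatched electrodes", len(dropped))

    results: List[ComparisonResult] = []
    change_rows = {"electrode_id": merged["electrode_id"]}
    for feat in feature_names:
        pre_vals = merged[f"{feat}_pre"].to_numpy(float)
        post_vals = merged[f"{feat}_post"].to_numpy(float)
        keep = np.isfinite(pre_vals) & np.isfinite(post_vals) & (pre_vals != 0)
        changes = 100.0 * (post_vals[keep] - pre_vals[keep]) / pre_vals[keep]
        u, p = mann_whitney_u(post_vals[keep], pre_vals[keep])
        results.append(
            ComparisonResult(
                feature_name=feat,
                n_pre=int(keep.sum()),
                n_post=int(keep.sum()),
                mean_pct_change=float(np.mean(changes)) if changes.size else np.nan,
                sd_pct_change=float(np.std(changes, ddof=1)) if changes.size > 1 else 0.0,
                u_statistic=u,
                p_value=p,
                significant=p < ALPHA,
            )
        )
        col = np.full(len(merged), np.nan)
        col[keep] = changes
        change_rows[f"{feat}_pct_change"] = col
    changes_df = pd.DataFrame(change_rows)

    # baseline stability: first baseline vs reference
    others = [k for k in baseline_tables if k != reference]
    if others:
        first = _intracellular(baseline_tables[sorted(others)[0]])
        stab = ref.merge(first, on="electrode_id", suffixes=("_ref", "_first"))
        for feat in feature_names:
            a = stab[f"{feat}_first"].to_numpy(float)
            b = stab[f"{feat}_ref"].to_numpy(float)
            keep = np.isfinite(a) & np.isfinite(b) & (a != 0)
            if keep.sum() == 0:
                continue
            deltas = 100.0 * (b[keep] - a[keep]) / a[keep]
            u, p = mann_whitney_u(b[keep], a[keep])
            results.append(
                ComparisonResult(
                    feature_name=f"{feat}_baseline_stability",
                    n_pre=int(keep.sum()),
                    n_post=int(keep.sum()),
                    mean_pct_change=float(np.mean(deltas)),
                    sd_pct_change=float(np.std(deltas, ddof=1)) if keep.sum() > 1 else 0.0,
                    u_statistic=u,
                    p_value=p,
                    significant=p < ALPHA,
                )
            )
    return results, changes_df


def _intracellular(table: pd.DataFrame) -> pd.DataFrame:
    sub = table[table["label"] == "intracellular_like"]
    return sub.drop_duplicates(subset="electrode_id", keep="first")
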