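"""Per-trial peak-response features and effect-size statistics.

The working feature is the peak response: for each trial and optode,
the extremum of the (filtered) concentration series in the 30 s
following trial onset, minus the value at onset (ΔHbO2, and
analogously ΔHHb).  On top of it sit

* the Effect Size Index (ESI) — the summed gap between one-standard-
  deviation intervals [μ_N − σ_N, μ_N + σ_N] of consecutive ordered
  load levels; negative when the intervals overlap;
* partial η² effect sizes from a two-way or repeated-measures ANOVA
  of the difficulty factor;
* per-optode paired-t maps for the high-minus-low load contrast.

Features live in a tidy DataFrame with columns ``subject_id, optode,
level, delta_hbo2, delta_hhb, onset_s``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

log = logging.getLogger(__name__)

__all__ = [
    "FEATURE_COLUMNS",
    "ESIResult",
    "EffectSizeResult",
    "TMap",
    "order_levels",
    "peak_response",
    "extract_trial_features",
    "compute_esi",
    "partial_eta_squared",
    "difficulty_anova",
    "contrast_tmap",
]

FEATURE_COLUMNS = ["subject_id", "optode", "level", "delta_hbo2", "delta_hhb", "onset_s"]

#: recognized non-numeric load orderings (lowest workload first)
_KNOWN_ORDERS = [("low", "high"), ("low", "medium", "high"), ("easy", "hard")]


def order_levels(values) -> list:
    """Sort load labels from lowest to highest workload.

    Numeric labels sort numerically; recognized verbal scales (e.g.
    low/high) use their semantic order; anything else falls back to
    lexicographic order.
    """
    uniq = list(pd.unique(pd.Series(list(values))))
    try:
        return sorted(uniq, key=float)
    except (TypeError, ValueError):
        pass
    lowered = {str(v).lower(): v for v in uniq}
    for known in _KNOWN_ORDERS:
        if set(lowered) == set(known):
            return [lowered[k] for k in known]
    return sorted(uniq, key=str)


def peak_response(
    signal: np.ndarray,
    onset: float,
    fs: float,
    window: float = 30.0,
    mode: str = "max",
) -> float:
    """Windowed extremum minus onset value of a single-channel series.

    The search window is half-open, ``(onset, onset + window]``; the
    onset value is taken at the first sample at or after ``onset``.
    ``mode="max"`` suits HbO2 (positive deflection), ``mode="min"``
    the typically negative HHb deflection.
    """
    signal = np.asarray(signal, dtype=float)
    n = signal.shape[0]
    if mode not in ("max", "min"):
        raise ValueError(f"mode must be 'max' or 'min', got {mode!r}")
    i0 = int(np.ceil(onset * fs - 1e-9))
    i_end = int(np.floor((onset + window) * fs + 1e-9))
    if onset < 0 or i0 >= n or i_end >= n:
        raise ValueError(
            f"window [{onset}, {onset + window}] s extends outside the "
            f"record (0..{(n - 1) / fs} s)"
        )
    base = signal[i0]
    seg = signal[i0 + 1: i_end + 1]
    ext = np.max(seg) if mode == "max" else np.min(seg)
    return float(ext - base)


def extract_trial_features(
    recording,
    events: pd.DataFrame,
    window: float = 30.0,
    hhb_mode: str = "max",
) -> pd.DataFrame:
    """One row of (ΔHbO2, ΔHHb) per (trial, optode).

    ``recording`` is a :class:`kalnirs.io.Recording` (raw or filtered —
    run the channels through a filter first to get filtered features).
    Trials whose 30 s window runs past the end of the record are
    dropped with a warning; overlapping windows are allowed.
    """
    ev = events.sort_values("onset").reset_index(drop=True)
    fs = recording.fs
    dur = recording.duration
    rows: list[dict] = []
    onsets = ev["onset"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) == 0):
        raise ValueError("events contain duplicate onsets")
    for _, trial in ev.iterrows():
        onset = float(trial["onset"])
        if onset + window > dur:
            log.warning(
                "dropping trial at onset %.1f s: %g s window exceeds "
                "record end %.1f s", onset, window, dur,
            )
            continue
        for k in range(1, recording.n_optodes + 1):
            hbo2 = recording.channel(f"O{k}_HbO2")
            hhb = recording.channel(f"O{k}_HHb")
            rows.append({
                "subject_id": trial.get("subject_id", recording.subject_id),
                "optode": k,
                "level": trial["condition"],
                "delta_hbo2": peak_response(hbo2, onset, fs, window, "max"),
                "delta_hhb": peak_response(hhb, onset, fs, window, hhb_mode),
                "onset_s": onset,
            })
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


@dataclass(frozen=True)
class ESIResult:
    """Separation of ordered load levels by 1-SD interval gaps."""

    levels: tuple
    means: tuple[float, ...]
    sds: tuple[float, ...]
    esi: float
    filter_label: str = ""
    qr_ratio: float | None = None
    optode: int | None = None


def compute_esi(
    features: pd.DataFrame,
    levels: list | None = None,
    measure: str = "delta_hbo2",
    by_subject: bool = True,
    **labels,
) -> ESIResult:
    """Effect Size Index over ordered load levels.

    For levels N1 < N2 < ... the ESI is
    ``Σ_i (μ_{N_{i+1}} − σ_{N_{i+1}}) − (μ_{N_i} + σ_{N_i})`` — e.g.
    for digit spans 5/7/9: ((μ7−σ7)−(μ5+σ5)) + ((μ9−σ9)−(μ7+σ7)).
    By default μ_N and σ_N are taken across subjects of per-subject
    mean features; ``by_subject=False`` pools all trials instead.
    """
    if levels is None:
        levels = order_levels(features["level"])
    if len(levels) < 2:
        raise ValueError("need at least 2 ordered levels for an ESI")
    mus, sds = [], []
    for lev in levels:
        sub = features[features["level"] == lev]
        if by_subject:
            vals = sub.groupby("subject_id")[measure].mean().to_numpy()
        else:
            vals = sub[measure].to_numpy()
        if len(vals) < 2:
            raise ValueError(
                f"level {lev!r} has {len(vals)} observation(s); need >= 2"
            )
        mus.append(float(np.mean(vals)))
        sds.append(float(np.std(vals, ddof=1)))
    esi = sum(
        (mus[i + 1] - sds[i + 1]) - (mus[i] + sds[i])
        for i in range(len(levels) - 1)
    )
    return ESIResult(
        levels=tuple(levels), means=tuple(mus), sds=tuple(sds),
        esi=float(esi), **labels,
    )


def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    """SS_effect / (SS_effect + SS_error)."""
    if ss_effect < 0 or ss_error < 0:
        raise ValueError("sums of squares must be non-negative")
    tot = ss_effect + ss_error
    if tot == 0:
        raise ValueError("both sums of squares are zero; effect size undefined")
    return float(ss_effect / tot)


@dataclass(frozen=True)
class EffectSizeResult:
    """Partial η² of the difficulty factor, per optode and pooled."""

    design: str
    per_optode: pd.DataFrame = field(repr=False)
    pooled: float = float("nan")
    pooled_ss_effect: float = float("nan")
    pooled_ss_error: float = float("nan")


def _rm_decompose(cell: pd.DataFrame) -> tuple[float, float]:
    """Within-subject SS decomposition on a subject × level mean table.

    Returns (SS_level, SS_subject×level); the interaction is the error
    stratum for the difficulty effect.
    """
    M = cell.to_numpy(dtype=float)
    grand = M.mean()
    m_subj = M.mean(axis=1, keepdims=True)
    m_lev = M.mean(axis=0, keepdims=True)
    n_s, n_l = M.shape
    ss_level = n_s * float(((m_lev - grand) ** 2).sum())
    ss_err = float(((M - m_subj - m_lev + grand) ** 2).sum())
    return ss_level, ss_err


def difficulty_anova(
    features: pd.DataFrame,
    design: str = "repeated_measures",
    measure: str = "delta_hbo2",
) -> EffectSizeResult:
    """Effect size of the load factor on the peak response.

    ``design="repeated_measures"``: per optode, subject × level cell
    means are decomposed within subject (error = subject-by-level
    interaction); the pooled value repeats the decomposition on
    per-subject means across all optodes.

    ``design="two_way"``: trial-level observations in an
    optode × level factorial fitted by OLS; partial η² of the level
    factor uses the residual SS as error.  Pooled = whole-table fit;
    per-optode values come from one-way fits within each optode.
    """
    if features["level"].nunique() < 2:
        raise ValueError("need at least two load levels")
    if design == "repeated_measures":
        if features["subject_id"].nunique() < 2:
            raise ValueError("repeated measures needs >= 2 subjects")
        rows = []
        for k, sub in features.groupby("optode"):
            cell = sub.pivot_table(
                index="subject_id", columns="level", values=measure,
                aggfunc="mean",
            )
            ss_l, ss_e = _rm_decompose(cell)
            rows.append({
                "optode": k, "ss_effect": ss_l, "ss_error": ss_e,
                "partial_eta_squared": partial_eta_squared(ss_l, ss_e)
                if (ss_l + ss_e) > 0 else 0.0,
            })
        per = pd.DataFrame(rows)
        pooled_cell = features.pivot_table(
            index="subject_id", columns="level", values=measure, aggfunc="mean"
        )
        ss_l, ss_e = _rm_decompose(pooled_cell)
    elif design == "two_way":
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        df = features.rename(columns={measure: "resp"}).copy()
        df["optode"] = df["optode"].astype("category")
        df["level"] = df["level"].astype(str).astype("category")
        fit = ols("resp ~ C(optode) + C(level) + C(optode):C(level)", df).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        ss_l = float(tab.loc["C(level)", "sum_sq"])
        ss_e = float(tab.loc["Residual", "sum_sq"])
        rows = []
        for k, sub in df.groupby("optode", observed=True):
            f1 = ols("resp ~ C(level)", sub).fit()
            t1 = sm.stats.anova_lm(f1, typ=2)
            sl = float(t1.loc["C(level)", "sum_sq"])
            se = float(t1.loc["Residual", "sum_sq"])
            rows.append({
                "optode": k, "ss_effect": sl, "ss_error": se,
                "partial_eta_squared": partial_eta_squared(sl, se)
                if (sl + se) > 0 else 0.0,
            })
        per = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown design {design!r}")
    pooled = partial_eta_squared(ss_l, ss_e) if (ss_l + ss_e) > 0 else 0.0
    return EffectSizeResult(
        design=design, per_optode=per, pooled=pooled,
        pooled_ss_effect=ss_l, pooled_ss_error=ss_e,
    )


@dataclass(frozen=True)
class TMap:
    """Per-optode paired-t contrast (high minus low load)."""

    table: pd.DataFrame  # optode, t, p, significant
    alpha: float
    high_label: object
    low_label: object

    def render_grid(self, n_cols: int = 8) -> str:
        """Plain-text 16-cell map (two rows of 8 by default);
        significant optodes are marked with ``*``."""
        cells = []
        for _, r in self.table.sort_values("optode").iterrows():
            mark = "*" if r["significant"] else " "
            cells.append(f"O{int(r['optode']):02d}:{r['t']:+6.2f}{mark}")
        lines = [
            "  ".join(cells[i: i + n_cols])
            for i in range(0, len(cells), n_cols)
        ]
        return "\n".join(lines)


def contrast_tmap(
    features: pd.DataFrame,
    high_label,
    low_label,
    alpha: float = 0.01,
    measure: str = "delta_hbo2",
) -> TMap:
    """Paired t across subjects of per-subject mean high−low response."""
    rows = []
    for k, sub in features.groupby("optode"):
        cell = sub.pivot_table(
            index="subject_id", columns="level", values=measure, aggfunc="mean"
        )
        for lab in (high_label, low_label):
            if lab not in cell.columns or cell[lab].isna().any():
                raise ValueError(f"label {lab!r} missing for some subject")
        diffs = (cell[high_label] - cell[low_label]).to_numpy(dtype=float)
        if len(diffs) < 3:
            raise ValueError("paired contrast needs >= 3 subjects")
        if np.std(diffs, ddof=1) == 0.0:
            # degenerate zero-variance contrast
            m = float(np.mean(diffs))
            t, p = (0.0, 1.0) if m == 0.0 else (np.sign(m) * np.inf, 0.0)
        else:
            t, p = spstats.ttest_1samp(diffs, 0.0)
        rows.append({
            "optode": k, "t": float(t), "p": float(p),
            "significant": bool(p < alpha),
        })
    return TMap(
        table=pd.DataFrame(rows), alpha=alpha,
        high_label=high_label, low_label=low_label,
    )
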