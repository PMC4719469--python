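"""Q/R tuning: sweep the noise-variance ratio and pick the best filter.

The state-to-measurement noise ratio Q/R is the one free parameter of
the model-based Kalman filters.  It is tuned by brute force: build
the filter at each point of a log-spaced grid spanning 1e-5..1e5, run
it over every optode's HbO2 (or HHb) series, extract per-trial peak
responses, score each optode by its Effect Size Index over the
ordered load levels, and keep the configuration with the highest ESI
(ties go to the smallest ratio).  The full score table is kept so the
selection can also be done by eye, and the winning configuration is
serializable for reuse on new data without re-optimization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import compute_esi, extract_trial_features
from .filters import build_kalman, run_kalman
from .hrf import HRFParameters, discretize_hrf, shift_stimulus
from .io import Recording
from .simulate import stimulus_train

log = logging.getLogger(__name__)

__all__ = ["SweepResult", "default_grid", "qr_sweep", "select_optimal"]

GRID_BOUNDS = (1e-5, 1e5)


def default_grid(n_points: int = 41) -> np.ndarray:
    """Log-spaced Q/R grid over the full sweep range 1e-5..1e5."""
    return np.geomspace(GRID_BOUNDS[0], GRID_BOUNDS[1], n_points)


@dataclass(frozen=True)
class SweepResult:
    """Score table of a Q/R sweep plus the winning configuration."""

    table: pd.DataFrame = field(repr=False)  # structure, qr_ratio, optode, measure, esi
    best_structure: str = ""
    best_qr_ratio: float = float("nan")
    best_optode: int = -1
    best_esi: float = float("nan")
    measure: str = "delta_hbo2"

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def _as_subject_list(data) -> list[tuple[Recording, pd.DataFrame]]:
    if isinstance(data, Recording):
        raise TypeError("pass (recording, events) pairs, not a bare Recording")
    if isinstance(data, tuple) and len(data) >= 2 and isinstance(data[0], Recording):
        return [(data[0], data[1])]
    return [(d[0], d[1]) for d in data]


def qr_sweep(
    data,
    structures: tuple[str, ...] = ("nominal", "augmented"),
    grid: np.ndarray | None = None,
    measure: str = "hbo2",
    hrf: HRFParameters | None = None,
    by_subject: bool | None = None,
) -> SweepResult:
    """Score every (structure, Q/R, optode) triple by ESI.

    ``data`` is a single ``(recording, events)`` pair or a list of
    them (one per subject).  ``measure`` selects the scored
    chromophore.  Grid points where the filter cannot be built are
    recorded as failed and skipped.  The sweep is deterministic.
    """
    pairs = _as_subject_list(data)
    if grid is None:
        grid = default_grid()
    grid = np.sort(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValueError("empty Q/R grid")
    if grid[0] < GRID_BOUNDS[0] * (1 - 1e-12) or grid[-1] > GRID_BOUNDS[1] * (1 + 1e-12):
        raise ValueError(f"grid must lie within {GRID_BOUNDS}")
    col = {"hbo2": "delta_hbo2", "hhb": "delta_hhb"}[measure]
    if by_subject is None:
        by_subject = len(pairs) > 1
    n_levels = pairs[0][1]["condition"].nunique()
    if n_levels < 2:
        raise ValueError("events must contain >= 2 load levels")
    if hrf is None:
        hrf = HRFParameters(fs=pairs[0][0].fs)
    model = discretize_hrf(hrf)

    shifted = [
        shift_stimulus(
            stimulus_train(ev, rec.n_samples, rec.fs), model.delay_samples
        )
        for rec, ev in pairs
    ]
    rows = []
    for structure in structures:
        for qr in grid:
            try:
                spec = build_kalman(model, structure, float(qr))
            except (RuntimeError, ValueError) as exc:
                log.warning("skipping %s @ Q/R=%g: %s", structure, qr, exc)
                for k in range(1, pairs[0][0].n_optodes + 1):
                    rows.append({
                        "structure": structure, "qr_ratio": float(qr),
                        "optode": k, "measure": measure,
                        "esi": np.nan, "failed": True,
                    })
                continue
            feats = []
            for (rec, ev), u in zip(pairs, shifted):
                which = "HbO2" if measure == "hbo2" else "HHb"
                out = run_kalman(spec, rec.chromophore(which), u)
                feats.append(extract_trial_features(
                    rec.with_channels(out.denoised, which), ev
                ))
            allfeat = pd.concat(feats, ignore_index=True)
            for k, sub in allfeat.groupby("optode"):
                res = compute_esi(sub, measure=col, by_subject=by_subject)
                rows.append({
                    "structure": structure, "qr_ratio": float(qr),
                    "optode": int(k), "measure": measure,
                    "esi": res.esi, "failed": False,
                })
    table = pd.DataFrame(rows)
    if table["failed"].all():
        raise RuntimeError("every grid point failed")
    best = _argmax(table)
    return SweepResult(
        table=table,
        best_structure=str(best["structure"]),
        best_qr_ratio=float(best["qr_ratio"]),
        best_optode=int(best["optode"]),
        best_esi=float(best["esi"]),
        measure=col,
    )


def _argmax(table: pd.DataFrame) -> pd.Series:
    ok = table[~table["failed"]]
    # np.argmax keeps the first maximum: sorting by (qr, optode) first
    # resolves ties toward the smallest ratio, then lowest optode index
    ok = ok.sort_values(["qr_ratio", "optode"], kind="mergesort")
    return ok.iloc[int(np.argmax(ok["esi"].to_numpy()))]


def select_optimal(sweep: SweepResult, aggregate: str = "best_optode") -> dict:
    """Deterministic filter configuration from a sweep.

    ``aggregate="best_optode"`` keeps the single best-scoring optode
    (mirroring tuning on the most responsive channel);
    ``aggregate="mean"`` scores each (structure, Q/R) by its mean ESI
    across optodes.  Returns a plain dict, YAML/JSON-serializable and
    consumable by the filter module.
    """
    ok = sweep.table[~sweep.table["failed"]]
    if ok.empty:
        raise RuntimeError("sweep contains no successful grid point")
    if aggregate == "best_optode":
        best = _argmax(sweep.table)
        cfg_optode = int(best["optode"])
        esi = float(best["esi"])
    elif aggregate == "mean":
        agg = (
            ok.groupby(["structure", "qr_ratio"])["esi"].mean().reset_index()
            .sort_values("qr_ratio", kind="mergesort")
        )
        best = agg.iloc[int(np.argmax(agg["esi"].to_numpy()))]
        cfg_optode = -1
        esi = float(best["esi"])
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return {
        "filter": {
            "kind": f"kalman_{best['structure']}",
            "qr_ratio": float(best["qr_ratio"]),
        },
        "optode": cfg_optode,
        "esi": esi,
        "measure": sweep.measure,
        "aggregate": aggregate,
    }
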