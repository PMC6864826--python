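"""Amdahl's-law speedup accounting and a per-row parallel detection runner.

For a workload with parallelizable fraction P run on N_p processors,
Amdahl's law bounds the speedup as S(N_p) = 1 / ((1 - P) + P / N_p).  The
inverse direction, P = (1 - 1/S) / (1 - 1/N_p), recovers the effectively
parallel fraction from a measured speedup; published performance tables are
derived in that inverse direction, so it is the reported statistic here.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass

import pandas as pd
from joblib import Parallel, delayed

from .detection import SeedingPoint, VegetationComponent, detect_seeding_points
from .errors import ValidationError


def amdahl_speedup(P: float, n_procs: int) -> float:
    """Speedup S(N_p) = 1 / ((1 - P) + P / N_p)."""
    if not (0.0 <= P <= 1.0):
        raise ValidationError(f"parallel fraction P={P} outside [0, 1]")
    if n_procs < 1:
        raise ValidationError("n_procs must be >= 1")
    return 1.0 / ((1.0 - P) + P / n_procs)


def parallel_fraction(S: float, n_procs: int) -> float:
    """Invert Amdahl's law: P = (1 - 1/S) / (1 - 1/N_p).

    A super-linear measured speedup (S > N_p) produces P > 1; it is returned
    with a warning rather than rejected, since measurement noise can cause it.
    """
    if S < 1.0:
        raise ValidationError("measured speedup must be >= 1")
    if n_procs < 2:
        raise ValidationError("n_procs must be >= 2 to estimate P")
    if S > n_procs:
        warnings.warn(f"super-linear speedup S={S} > N_p={n_procs}", stacklevel=2)
    return (1.0 - 1.0 / S) / (1.0 - 1.0 / n_procs)


@dataclass
class SpeedupRecord:
    """One row of a speedup table."""

    n_procs: int
    time_min: float
    speedup: float
    parallel_fraction: float

    @property
    def serial_fraction(self) -> float:
        return 1.0 - self.parallel_fraction


def speedup_table(times_min: dict[int, float]) -> pd.DataFrame:
    """Amdahl table (N_p, time, S, P, 1-P) from measured times keyed by N_p."""
    if 1 not in times_min:
        raise ValidationError("need the single-process time (key 1) as the baseline")
    t1 = times_min[1]
    rows = []
    for n in sorted(times_min):
        s = t1 / times_min[n]
        p = 0.0 if n == 1 else round(parallel_fraction(s, n), 4)
        rows.append({"n_procs": n, "time_min": times_min[n], "speedup": round(s, 4),
                     "parallel_fraction": p, "serial_fraction": round(1 - p, 4)})
    return pd.DataFrame(rows)


def run_parallel(
    groups: dict[int, list[VegetationComponent]],
    worker_count: int = 1,
    d: float = 0.3,
    max_iter: int = 20,
    seed: int = 0,
) -> tuple[list[SeedingPoint], list[dict]]:
    """Detect seeding points per row group, optionally on parallel workers.

    Groups must be pairwise disjoint (guaranteed by ``partition_rows``), which
    removes any data dependency between workers; the merged output is
    set-equal to a serial run because each component's random stream depends
    only on the base seed and its component id.  Returns the merged points
    (sorted by component id then coordinates) and a per-group timing log for
    user-side Amdahl analysis.
    """

    def _one(row_id: int, comps: list[VegetationComponent]):
        t0 = time.perf_counter()
        pts = detect_seeding_points(comps, d=d, max_iter=max_iter, seed=seed)
        return row_id, pts, time.perf_counter() - t0

    items = sorted(groups.items())
    if worker_count <= 1:
        results = [_one(rid, comps) for rid, comps in items]
    else:
        results = Parallel(n_jobs=worker_count)(delayed(_one)(rid, comps) for rid, comps in items)
    points: list[SeedingPoint] = []
    log = []
    for row_id, pts, dt in results:
        points.extend(pts)
        log.append({"row_id": row_id, "n_points": len(pts), "seconds": dt})
    points.sort(key=lambda p: (p.component_id, p.x, p.y))
    return points, log
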