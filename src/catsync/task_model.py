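"""Geometry and behavior of the delayed match-to-spatial-category task.

A sample dot appears in one of 144 locations (16 base positions, four per
visual quadrant, crossed with a ±0.5° per-axis jitter) and is categorized
Above or Below the horizontal meridian.  After a delay the two
hemi-boundaries reappear shifted by ±4° (clockwise: left half-boundary up,
right half-boundary down; counter-clockwise reversed), and a test stimulus
drawn from a 624-location grid must be matched to the *sample's original
category* judged against the *shifted* boundaries.  The sample's own
category never changes with the shift; only the retinotopic area each
category occupies does.

Conventions: degrees of visual angle, x positive rightward, y positive
upward, origin at fixation.  "Above" uses a strict inequality; stimuli are
never displayed exactly on a boundary or on the vertical meridian.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal

import numpy as np
import pandas as pd

Category = Literal["Above", "Below"]
Hemifield = Literal["Left", "Right"]
Shift = Literal["CW", "CCW"]

#: Factors accepted by :func:`accuracy_breakdown`.
BREAKDOWN_FACTORS = (
    "eccentricity",
    "meridian_distance",
    "hemifield",
    "quadrant",
    "sample_test_distance",
    "boundary_proximal_flip",
)


def _default_base_grid() -> tuple[tuple[float, float], ...]:
    # Four positions per quadrant; the |y| = 2 rows sit proximal to the
    # boundary so that a ±4° shift flips their side of the line.
    return tuple(
        (float(sx * ax), float(sy * ay))
        for sx in (-1, 1)
        for sy in (-1, 1)
        for ax in (3.0, 6.0)
        for ay in (2.0, 5.0)
    )


def _default_test_grid() -> tuple[tuple[float, float], ...]:
    # 26 columns x 24 rows = 624 locations on half-integer coordinates,
    # mirror-symmetric about both meridians and never on a (shifted)
    # boundary.
    xs = [s * (0.5 + i) for s in (-1, 1) for i in range(13)]
    ys = [s * (0.5 + i) for s in (-1, 1) for i in range(12)]
    return tuple((float(x), float(y)) for x in sorted(xs) for y in sorted(ys))


@dataclass(frozen=True)
class TaskGeometry:
    """Sample/test grids, jitter and boundary-shift magnitude."""

    base_sample_positions: tuple[tuple[float, float], ...] = field(
        default_factory=_default_base_grid
    )
    jitter_levels: tuple[float, ...] = (-0.5, 0.0, 0.5)
    test_positions: tuple[tuple[float, float], ...] = field(
        default_factory=_default_test_grid
    )
    shift_magnitude: float = 4.0
    fixation_radius: float = 1.5

    def __post_init__(self) -> None:
        if not self.jitter_levels:
            raise ValueError("jitter_levels must be non-empty")
        if len(self.jitter_levels) % 2 == 0:
            raise ValueError("jitter_levels must have odd length (include 0)")
        lv = np.sort(np.asarray(self.jitter_levels, float))
        if not np.allclose(lv, -lv[::-1]):
            raise ValueError("jitter_levels must be symmetric about 0")
        base = np.asarray(self.base_sample_positions, float)
        if len(self.base_sample_positions) != len(set(self.base_sample_positions)):
            raise ValueError("base sample positions must be distinct")
        if np.any(base[:, 0] == 0) or np.any(base[:, 1] == 0):
            raise ValueError("base sample positions must avoid both meridians")
        if np.any(np.hypot(base[:, 0], base[:, 1]) <= self.fixation_radius):
            raise ValueError("base sample positions must lie outside fixation window")
        mirrored_x = {(-x, y) for x, y in self.base_sample_positions}
        mirrored_y = {(x, -y) for x, y in self.base_sample_positions}
        if mirrored_x != set(self.base_sample_positions) or mirrored_y != set(
            self.base_sample_positions
        ):
            raise ValueError("base grid must be mirror-symmetric across both meridians")

    def shifted_boundaries(self, shift: Shift) -> tuple[float, float]:
        """Return (left boundary y, right boundary y) after a CW/CCW shift."""
        m = self.shift_magnitude
        if shift == "CW":
            return (m, -m)
        if shift == "CCW":
            return (-m, m)
        raise ValueError(f"unknown shift {shift!r}")


def enumerate_sample_locations(geometry: TaskGeometry) -> set[tuple[float, float]]:
    """All distinct sample locations = base grid x per-axis jitter.

    With 16 base positions and the default 3-level jitter this yields the
    144 distinct sample locations of the task.
    """
    locs: set[tuple[float, float]] = set()
    for (bx, by), jx, jy in itertools.product(
        geometry.base_sample_positions, geometry.jitter_levels, geometry.jitter_levels
    ):
        locs.add((round(bx + jx, 9), round(by + jy, 9)))
    expected = len(geometry.base_sample_positions) * len(geometry.jitter_levels) ** 2
    if len(locs) != expected:
        raise ValueError(
            "sample grid misconfigured: jittered locations from distinct base "
            f"positions overlap ({len(locs)} != {expected})"
        )
    return locs


def enumerate_sample_test_pairs(
    geometry: TaskGeometry,
) -> tuple[int, Iterator[tuple[tuple[float, float], tuple[float, float]]]]:
    """Count and iterate all (sample, test) location pairs.

    Default task: 144 samples x 624 tests = 89,856 combinations.
    """
    samples = sorted(enumerate_sample_locations(geometry))
    tests = geometry.test_positions
    if not samples or not tests:
        raise ValueError("sample and test grids must be non-empty")
    count = len(samples) * len(tests)
    return count, itertools.product(samples, tests)


def categorize_location(
    xy: tuple[float, float], boundary_y_left: float, boundary_y_right: float
) -> Category:
    """Above/Below category of a location against per-hemifield boundaries."""
    x, y = xy
    if x == 0:
        raise ValueError("location on the vertical meridian has no hemi-boundary")
    boundary = boundary_y_left if x < 0 else boundary_y_right
    if y == boundary:
        raise ValueError("location exactly on the category boundary is never shown")
    return "Above" if y > boundary else "Below"


def evaluate_match(
    trial_sample: tuple[float, float],
    shift: Shift,
    test_xy: tuple[float, float],
    geometry: TaskGeometry,
) -> Literal["match", "nonmatch"]:
    """Boundary-referenced match rule.

    The sample is categorized against the original meridian (boundaries at
    0), the test against the shifted boundaries; they match iff the two
    categories agree.  The shift never alters the sample's own category.
    """
    sample_cat = categorize_location(trial_sample, 0.0, 0.0)
    bl, br = geometry.shifted_boundaries(shift)
    test_cat = categorize_location(test_xy, bl, br)
    return "match" if sample_cat == test_cat else "nonmatch"


# ---------------------------------------------------------------------------
# Behavior tables
# ---------------------------------------------------------------------------

#: Column schema of a behavior table (one row per trial).
TRIAL_COLUMNS = [
    "trial",
    "sample_x",
    "sample_y",
    "category_ab",
    "hemifield_lr",
    "shift",
    "test1_x",
    "test1_y",
    "test1_is_match",
    "response1",
    "correct",
]


def make_trial_table(
    geometry: TaskGeometry,
    n_trials: int,
    rng: np.random.Generator,
    lapse_rate: float = 0.07,
) -> pd.DataFrame:
    """Simulate a behavioral session.

    Trials are balanced across the 8 cells of Above/Below x Left/Right x
    CW/CCW; sample locations are drawn uniformly within each cell; the
    first test is a match on half of the trials.  The simulated observer
    responds to the true match status except on a fraction ``lapse_rate``
    of trials where the response is flipped; ``correct`` records whether
    the first-test response followed the task contingency.
    """
    samples = sorted(enumerate_sample_locations(geometry))
    sx = np.array([p[0] for p in samples])
    sy = np.array([p[1] for p in samples])
    cells = {}
    for ab in ("Above", "Below"):
        for lr in ("Left", "Right"):
            mask = ((sy > 0) == (ab == "Above")) & ((sx < 0) == (lr == "Left"))
            cells[(ab, lr)] = np.flatnonzero(mask)

    tests = np.asarray(geometry.test_positions, float)
    rows = []
    combos = [
        (ab, lr, sh)
        for ab in ("Above", "Below")
        for lr in ("Left", "Right")
        for sh in ("CW", "CCW")
    ]
    for i in range(n_trials):
        ab, lr, sh = combos[i % len(combos)]
        k = rng.choice(cells[(ab, lr)])
        sample = (float(sx[k]), float(sy[k]))
        bl, br = geometry.shifted_boundaries(sh)
        boundary = np.where(tests[:, 0] < 0, bl, br)
        test_above = tests[:, 1] > boundary
        want_match = bool(rng.integers(2))
        pool = tests[test_above == (ab == "Above")] if want_match else tests[
            test_above != (ab == "Above")
        ]
        t = pool[rng.integers(len(pool))]
        is_match = want_match
        respond_go = is_match
        if rng.random() < lapse_rate:
            respond_go = not respond_go
        correct = respond_go == is_match
        rows.append(
            dict(
                trial=i,
                sample_x=sample[0],
                sample_y=sample[1],
                category_ab=ab,
                hemifield_lr=lr,
                shift=sh,
                test1_x=float(t[0]),
                test1_y=float(t[1]),
                test1_is_match=is_match,
                response1="Go" if respond_go else "NoGo",
                correct=correct,
            )
        )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def _implied_judgment(
    table: pd.DataFrame, geometry: TaskGeometry, dimension: str
) -> pd.Series:
    """Category judgment implied by each first-test response.

    A Go response asserts the test matched the sample category, so the
    implied sample category equals the test's category (in the shifted
    frame for Above/Below); a No-go asserts the opposite.  For the
    task-irrelevant Left/Right dimension the same logic is applied to the
    test's hemifield, which an observer tracking only Above/Below renders
    at chance.
    """
    out = []
    for _, r in table.iterrows():
        if dimension == "above_below":
            bl, br = geometry.shifted_boundaries(r["shift"])
            test_cat = categorize_location((r["test1_x"], r["test1_y"]), bl, br)
            positive = test_cat == "Above"
        elif dimension == "left_right":
            positive = r["test1_x"] < 0
        else:
            raise ValueError(f"unknown dimension {dimension!r}")
        go = r["response1"] == "Go"
        out.append(positive if go else not positive)
    return pd.Series(out, index=table.index)


def p_above_map(
    table: pd.DataFrame, geometry: TaskGeometry | None = None
) -> pd.DataFrame:
    """Per sample location, P(judged Above) and P(judged Left).

    Returns a frame indexed by (sample_x, sample_y) with columns
    ``p_above``, ``p_below`` (= 1 - p_above), ``p_left``, ``p_right`` and
    ``n``.  Locations with zero trials are simply absent (never imputed).
    """
    geometry = geometry or TaskGeometry()
    if table.empty:
        raise ValueError("empty behavior table")
    tab = table.copy()
    tab["judged_above"] = _implied_judgment(tab, geometry, "above_below")
    tab["judged_left"] = _implied_judgment(tab, geometry, "left_right")
    grp = tab.groupby(["sample_x", "sample_y"])
    out = grp.agg(
        p_above=("judged_above", "mean"),
        p_left=("judged_left", "mean"),
        n=("trial", "size"),
    )
    out["p_below"] = 1.0 - out["p_above"]
    out["p_right"] = 1.0 - out["p_left"]
    return out[["p_above", "p_below", "p_left", "p_right", "n"]]


def _flip_levels(table: pd.DataFrame, geometry: TaskGeometry) -> pd.Series:
    """Among boundary-proximal samples (base |y| = 2), whether the sample's
    retinotopic location lands on the other side of the shifted boundary."""
    lev = pd.Series(pd.NA, index=table.index, dtype=object)
    near = (table["sample_y"].abs() - 2.0).abs() <= 0.5 + 1e-9
    for i in table.index[near]:
        r = table.loc[i]
        bl, br = geometry.shifted_boundaries(r["shift"])
        post = categorize_location((r["sample_x"], r["sample_y"]), bl, br)
        lev[i] = "flipped" if post != r["category_ab"] else "unflipped"
    return lev


def accuracy_breakdown(
    table: pd.DataFrame, factor: str, geometry: TaskGeometry | None = None
) -> pd.DataFrame:
    """Accuracy per level of a stimulus factor.

    ``boundary_proximal_flip`` restricts to samples whose base row sits at
    |y| = 2 and splits by whether the boundary shift moved the sample's own
    retinotopic position across the relevant hemi-boundary.
    """
    geometry = geometry or TaskGeometry()
    if factor not in BREAKDOWN_FACTORS:
        raise ValueError(f"unknown factor {factor!r}; expected one of {BREAKDOWN_FACTORS}")
    tab = table.copy()
    if factor == "eccentricity":
        tab["level"] = np.round(np.hypot(tab["sample_x"], tab["sample_y"]), 1)
    elif factor == "meridian_distance":
        tab["level"] = np.round(tab["sample_y"].abs(), 1)
    elif factor == "hemifield":
        tab["level"] = tab["hemifield_lr"]
    elif factor == "quadrant":
        tab["level"] = tab["category_ab"].str[0] + tab["hemifield_lr"].str[0]
    elif factor == "sample_test_distance":
        d = np.hypot(tab["sample_x"] - tab["test1_x"], tab["sample_y"] - tab["test1_y"])
        tab["level"] = pd.cut(d, bins=[0, 5, 10, 15, np.inf], labels=["0-5", "5-10", "10-15", ">15"])
    elif factor == "boundary_proximal_flip":
        tab["level"] = _flip_levels(tab, geometry)
        tab = tab[tab["level"].notna()]
    grp = tab.groupby("level", observed=True)
    out = grp.agg(accuracy=("correct", "mean"), n=("correct", "size")).reset_index()
    return out
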