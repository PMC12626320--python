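import itertools

import numpy as np
import pytest

from wormtrack.behavior import Trajectory


def make_trajectory(x, y, fps=25.0, w=None, h=None, track_id=0):
    """Trajectory from coordinate arrays with unit box dims by default."""
    x = np.asarray(x, dtype=float)
    t = np.arange(len(x)) / fps
    return Trajectory(
        track_id=track_id,
        t=t,
        x=x,
        y=np.asarray(y, dtype=float),
        w=np.full(len(x), 10.0) if w is None else np.asarray(w, dtype=float),
        h=np.full(len(x), 10.0) if h is None else np.asarray(h, dtype=float),
        fps=fps,
    )


def make_loop_trajectory(radius, sweep_deg=300.0, straight=200.0, speed=50.0,
                         fps=25.0, n_loops=1, gap=None, ccw=True):
    """Constant-speed path: straight run, n tight arcs, straight runs between.

    ``gap`` is the straight path length between consecutive loops (defaults
    to ``straight``). Returns a Trajectory sampled at ``fps``.
    """
    if gap is None:
        gap = straight
    step = speed / fps
    pts = [np.array([0.0, 0.0])]
    heading = 0.0
    sign = 1.0 if ccw else -1.0

    def advance_straight(dist):
        nonlocal heading
        n = int(round(dist / step))
        for _ in range(n):
            pts.append(pts[-1] + step * np.array([np.cos(heading), np.sin(heading)]))

    def advance_arc():
        nonlocal heading
        arc_len = np.radians(sweep_deg) * radius
        n = int(round(arc_len / step))
        dpsi = sign * step / radius
        for _ in range(n):
            heading += dpsi
            pts.append(pts[-1] + step * np.array([np.cos(heading), np.sin(heading)]))

    advance_straight(straight)
    for i in range(n_loops):
        advance_arc()
        advance_straight(gap if i < n_loops - 1 else straight)
    pts = np.array(pts)
    return make_trajectory(pts[:, 0], pts[:, 1], fps=fps)


def brute_force_assignment_cost(costs):
    """Minimum total cost over all maximal matchings, by enumeration."""
    costs = np.asarray(costs, dtype=float)
    n_rows, n_cols = costs.shape
    k = min(n_rows, n_cols)
    best = np.inf
    rows = range(n_rows)
    cols = range(n_cols)
    for row_subset in itertools.combinations(rows, k):
        for col_perm in itertools.permutations(cols, k):
            total = sum(costs[i, j] for i, j in zip(row_subset, col_perm))
            best = min(best, total)
    return best


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
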