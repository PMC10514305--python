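"""Independent brute-force oracles used to cross-check the pipeline.

These deliberately avoid the production code paths: the permeation oracle
matches *patterns* on the compressed region sequence instead of running a
stateful detector, and the superposition oracle minimises the sum of squared
displacements numerically over a rotation-vector parameterisation.
"""

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def region_codes(pts, radius, z_lo, z_hi):
    """Region letters for one molecule's (F, 3) track: b/i/a/l."""
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    lateral = x * x + y * y > radius * radius
    return np.select(
        [lateral, z < z_lo, z > z_hi], ["l", "b", "a"], default="i"
    )


def _jump_ok(p0, p1, radius, z_lo, z_hi, box):
    """Does the (minimum-image) straight path cross both faces in-radius?"""
    p1 = p1.astype(float).copy()
    if box is not None:
        b = np.asarray(box, dtype=float)
        disp = p1 - p0
        p1 = p0 + disp - b * np.round(disp / b)
    if not ((p0[2] < z_lo and p1[2] > z_hi) or (p0[2] > z_hi and p1[2] < z_lo)):
        return False, 0
    dz = p1[2] - p0[2]
    for z_face in (z_lo, z_hi):
        s = (z_face - p0[2]) / dz
        if not 0 <= s <= 1:
            return False, 0
        xx = p0[0] + s * (p1[0] - p0[0])
        yy = p0[1] + s * (p1[1] - p0[1])
        if np.hypot(xx, yy) > radius:
            return False, 0
    return True, 1 if p1[2] > p0[2] else -1


def event_list_bruteforce(positions, radius=2.0, z_lo=-0.6, z_hi=0.6, box=None):
    """Per-molecule (molecule, exit_frame, direction) by pattern matching.

    Compress each molecule's region sequence to runs of distinct regions;
    every adjacent (side, inside-run, opposite-side) triple is one event —
    a lateral run in between breaks the pattern, which is exactly the
    disarm rule.  Direct side-to-side jumps between adjacent frames count
    only when the minimum-image straight path crosses both axial faces
    within the radius.
    """
    F, M, _ = positions.shape
    events = []
    for m in range(M):
        pts = positions[:, m, :]
        codes = region_codes(pts, radius, z_lo, z_hi)
        change = np.nonzero(codes[1:] != codes[:-1])[0] + 1
        run_starts = np.concatenate([[0], change])
        run_codes = codes[run_starts]
        for k in range(1, len(run_codes) - 1):
            if (
                run_codes[k] == "i"
                and {run_codes[k - 1], run_codes[k + 1]} == {"b", "a"}
            ):
                f_exit = run_starts[k + 1]
                events.append(
                    (m, int(f_exit), 1 if run_codes[k + 1] == "a" else -1)
                )
        for f in change:
            pair = codes[f - 1] + codes[f]
            if pair in ("ba", "ab"):
                ok, direction = _jump_ok(
                    pts[f - 1].astype(float), pts[f], radius, z_lo, z_hi, box
                )
                if ok:
                    events.append((m, int(f), direction))
    return sorted(events)


def count_crossings_bruteforce(positions, radius=2.0, z_lo=-0.6, z_hi=0.6, box=None):
    """Total and per-direction crossing counts (see event_list_bruteforce)."""
    events = event_list_bruteforce(positions, radius, z_lo, z_hi, box)
    per_dir = {1: 0, -1: 0}
    for _, _, d in events:
        per_dir[d] += 1
    return len(events), per_dir


def superpose_numeric(mobile, reference):
    """Numerically minimise RMSD over rotation vector + translation."""
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)

    def cost(theta):
        R = Rotation.from_rotvec(theta[:3]).as_matrix()
        moved = mobile @ R.T + theta[3:]
        return np.sum((moved - reference) ** 2)

    best = None
    for trial in range(8):
        rng = np.random.default_rng(trial)
        x0 = np.concatenate([rng.normal(0, 1, 3), reference.mean(0) - mobile.mean(0)])
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000})
        if best is None or res.fun < best.fun:
            best = res
    return float(np.sqrt(best.fun / len(mobile)))
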