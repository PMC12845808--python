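import numpy as np
import pytest

import pigpen as pp


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def noise_free_scene():
    """A deterministic noise-free scene shared by mask-recovery tests."""
    cfg = pp.seen_config(noise_std=0.0)
    return cfg, pp.generate_scene(cfg, seed=3)


def brute_force_otsu(gray: np.ndarray) -> int:
    """Exhaustive search over all 256 thresholds maximizing inter-class
    variance (smallest-t tie-break); independent of the implementation.
    A constant image returns its single value (empty foreground convention)."""
    if gray.min() == gray.max():
        return int(gray.min())
    hist = np.bincount(gray.ravel(), minlength=256).astype(float)
    n = hist.sum()
    levels = np.arange(256)
    best_t, best_v = 0, -1.0
    for t in range(256):
        w0 = hist[: t + 1].sum()
        w1 = n - w0
        if w0 == 0 or w1 == 0:
            v = 0.0
        else:
            mu0 = (hist[: t + 1] * levels[: t + 1]).sum() / w0
            mu1 = (hist[t + 1 :] * levels[t + 1 :]).sum() / w1
            v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


def max_assignment_tp(iou_matrix: np.ndarray, thr: float) -> int:
    """Maximum one-to-one matching size over all assignments (exhaustive)."""
    n_det, n_gt = iou_matrix.shape
    ok = iou_matrix >= thr

    def rec(d: int, used: int) -> int:
        if d == n_det:
            return 0
        best = rec(d + 1, used)
        for g in range(n_gt):
            if ok[d, g] and not used & (1 << g):
                best = max(best, 1 + rec(d + 1, used | (1 << g)))
        return best

    return rec(0, 0)
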