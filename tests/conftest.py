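import numpy as np
import pytest

from segconcord import MaskVolume


@pytest.fixture
def make_mask():
    """Factory for small MaskVolume objects from arrays or voxel counts."""

    def _make(arr=None, shape=(10, 10, 10), n_foreground=0, spacing=(1.0, 1.0, 1.0),
              seed=None, case_id="case"):
        if arr is None:
            arr = np.zeros(shape, dtype=np.uint8)
            if n_foreground:
                flat = arr.ravel()
                if seed is None:
                    flat[:n_foreground] = 1
                else:
                    rng = np.random.default_rng(seed)
                    idx = rng.choice(flat.size, size=n_foreground, replace=False)
                    flat[idx] = 1
        return MaskVolume(voxels=np.asarray(arr), spacing=spacing, case_id=case_id)

    return _make


def brute_force_counts(gt, cmp):
    """Independent voxel-by-voxel confusion tally (pure Python loops)."""
    a, b = gt.voxels, cmp.voxels
    tp = fp = fn = tn = 0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            for k in range(a.shape[2]):
                g, c = a[i, j, k], b[i, j, k]
                if g and c:
                    tp += 1
                elif c:
                    fp += 1
                elif g:
                    fn += 1
                else:
                    tn += 1
    return tp, fp, fn, tn
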