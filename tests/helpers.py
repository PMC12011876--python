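"""Shared test utilities: numerical gradient checking."""

import numpy as np

from amsmlp.autodiff import Tensor


def numeric_grad(fn, arrays, wrt, eps=1e-5, max_entries=None, rng=None):
    """Central-difference gradient of ``fn(arrays).sum()`` w.r.t. arrays[wrt].

    ``fn`` maps plain float64 numpy arrays to a float64 numpy array. Returns a
    flat array of numeric derivatives for the checked entries and their flat
    indices.
    """
    a = [np.array(x, dtype=np.float64) for x in arrays]
    target = a[wrt]
    idxs = np.arange(target.size)
    if max_entries is not None and target.size > max_entries:
        rng = rng or np.random.default_rng(0)
        idxs = rng.choice(target.size, size=max_entries, replace=False)
    grads = np.empty(len(idxs))
    flat = target.reshape(-1)
    for k, i in enumerate(idxs):
        orig = flat[i]
        flat[i] = orig + eps
        hi = fn(*a).sum()
        flat[i] = orig - eps
        lo = fn(*a).sum()
        flat[i] = orig
        grads[k] = (hi - lo) / (2 * eps)
    return grads, idxs


def check_grads(op, arrays, atol=1e-6, rtol=1e-4, max_entries=50, rng=None):
    """Compare autodiff gradients of ``op`` against central differences.

    ``op`` takes Tensors and returns a Tensor; ``arrays`` are float64 inputs.
    Every input is checked.
    """
    tensors = [Tensor(np.array(x, dtype=np.float64), requires_grad=True)
               for x in arrays]
    out = op(*tensors)
    out.sum().backward()

    def as_numpy_fn(*plain):
        return op(*[Tensor(p) for p in plain]).data

    for wrt, t in enumerate(tensors):
        num, idxs = numeric_grad(
            as_numpy_fn, arrays, wrt, max_entries=max_entries, rng=rng
        )
        ana = t.grad.reshape(-1)[idxs]
        np.testing.assert_allclose(
            ana, num, atol=atol, rtol=rtol,
            err_msg=f"gradient mismatch for input {wrt}",
        )
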