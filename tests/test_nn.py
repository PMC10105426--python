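"""Engine-level checks: the autodiff primitives against independent oracles."""

import numpy as np
import pytest
from thyroseg import nn
from thyroseg.nn import functional as F
from thyroseg.nn.tensor import Tensor


def dense_conv_oracle(x, w, pad, dilation=1, groups=1):
    """Brute-force correlation: explicit loops over output positions."""
    B, Cin, H, W = x.shape
    Cout, cg, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Ho = xp.shape[2] - (kh - 1) * dilation
    Wo = xp.shape[3] - (kw - 1) * dilation
    out = np.zeros((B, Cout, Ho, Wo))
    cog = Cout // groups
    for b in range(B):
        for o in range(Cout):
            g = o // cog
            for i in range(Ho):
                for j in range(Wo):
                    acc = 0.0
                    for c in range(cg):
                        for u in range(kh):
                            for v in range(kw):
                                acc += (
                                    w[o, c, u, v]
                                    * xp[b, g * cg + c, i + u * dilation, j + v * dilation]
                                )
                    out[b, o, i, j] = acc
    return out


@pytest.mark.parametrize(
    "cin,cout,k,pad,dil,groups",
    [(3, 4, 3, 1, 1, 1), (4, 4, 3, 2, 2, 2), (2, 6, 5, 0, 1, 1), (4, 8, 1, 0, 1, 4)],
)
def test_conv2d_matches_bruteforce(rng, cin, cout, k, pad, dil, groups):
    x = rng.normal(size=(2, cin, 7, 8)).astype(np.float32)
    w = rng.normal(size=(cout, cin // groups, k, k)).astype(np.float32)
    got = F.conv2d(Tensor(x), Tensor(w), padding=pad, dilation=dil, groups=groups).data
    want = dense_conv_oracle(x, w, pad, dil, groups)
    assert got.shape == want.shape
    np.testing.assert_allclose(got, want, atol=1e-4)


def _fd_grads(fn, tensors, h=1e-2):
    """Central finite differences in the perturbed forward graph."""
    out = fn()
    out.sum().backward()
    grads = [t.grad.copy() for t in tensors]
    for t in tensors:
        t.grad = None
    num = []
    for t in tensors:
        g = np.zeros_like(t.data)
        it = np.nditer(t.data, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = t.data[i]
            t.data[i] = orig + h
            lp = float(fn().sum().data)
            t.data[i] = orig - h
            lm = float(fn().sum().data)
            t.data[i] = orig
            g[i] = (lp - lm) / (2 * h)
        num.append(g)
    return grads, num


@pytest.mark.parametrize(
    "name,builder",
    [
        ("conv", lambda x, c: F.conv2d(x, c, padding="same")),
        ("avgpool", lambda x, c: F.avg_pool2d(x * c.sum())),
        ("resize_up", lambda x, c: F.bilinear_resize(x, (9, 11)) * c.sum()),
        ("softmax", lambda x, c: F.softmax(x, 1) * c),
        ("log_softmax", lambda x, c: F.log_softmax(x, 1) * c),
    ],
)
def test_primitive_gradients_match_finite_differences(rng, name, builder):
    x = Tensor(rng.normal(size=(1, 3, 5, 6)).astype(np.float32), requires_grad=True)
    shape = (1, 3, 3, 3) if name == "conv" else (1, 3, 5, 6)
    c = Tensor(rng.normal(size=shape).astype(np.float32) * 0.5, requires_grad=True)
    grads, num = _fd_grads(lambda: builder(x, c), [x, c])
    for g, n in zip(grads, num):
        np.testing.assert_allclose(g, n, atol=5e-2, rtol=5e-2)


def test_batchnorm_train_normalizes_and_eval_uses_running_stats(rng):
    bn = nn.BatchNorm2d(3, momentum=1.0)
    x = Tensor(rng.normal(2.0, 3.0, size=(4, 3, 8, 8)).astype(np.float32))
    y = bn(x)
    assert np.allclose(y.data.mean(axis=(0, 2, 3)), 0, atol=1e-5)
    assert np.allclose(y.data.std(axis=(0, 2, 3)), 1, atol=1e-3)
    bn.eval()
    y2 = bn(x)  # eval path: affine with the stored statistics
    np.testing.assert_allclose(y2.data, y.data, atol=2e-2)


def test_bilinear_resize_identity_and_constant_preservation(rng):
    x = Tensor(rng.normal(size=(1, 2, 6, 6)).astype(np.float32))
    np.testing.assert_allclose(F.bilinear_resize(x, (6, 6)).data, x.data)
    const = Tensor(np.full((1, 1, 1, 1), 3.5, dtype=np.float32))
    up = F.bilinear_resize(const, (7, 5)).data
    np.testing.assert_allclose(up, 3.5)


def test_max_pool_routes_gradient_to_argmax(rng):
    x = Tensor(rng.permutation(24).reshape(1, 1, 4, 6).astype(np.float32), requires_grad=True)
    y = F.max_pool2d(x)
    y.backward(np.ones(y.shape, dtype=np.float32))
    # each 2x2 window: gradient 1 exactly at its maximum, 0 elsewhere
    for i in range(2):
        for j in range(3):
            win = x.data[0, 0, 2 * i:2 * i + 2, 2 * j:2 * j + 2]
            gwin = x.grad[0, 0, 2 * i:2 * i + 2, 2 * j:2 * j + 2]
            assert gwin.sum() == 1.0
            assert gwin[np.unravel_index(win.argmax(), win.shape)] == 1.0


@pytest.mark.parametrize("hw", [(8, 10), (7, 9)])
def test_pooling_matches_window_loop_oracle(rng, hw):
    x = rng.normal(size=(1, 1, *hw)).astype(np.float32)
    got_max = F.max_pool2d(Tensor(x)).data[0, 0]
    got_avg = F.avg_pool2d(Tensor(x)).data[0, 0]
    H, W = hw
    for i in range(got_max.shape[0]):
        for j in range(got_max.shape[1]):
            win = x[0, 0, 2 * i:min(2 * i + 2, H), 2 * j:min(2 * j + 2, W)]
            assert got_max[i, j] == win.max()
            assert abs(got_avg[i, j] - win.mean()) < 1e-6


def test_no_grad_blocks_graph_recording(rng):
    x = Tensor(rng.normal(size=(2, 2)).astype(np.float32), requires_grad=True)
    with nn.no_grad():
        y = (x * 2.0).sum()
    assert y._backward is None and not y.requires_grad


def test_adamw_decoupled_weight_decay_shrinks_parameters():
    p = Tensor(np.full(4, 10.0, dtype=np.float32), requires_grad=True)
    opt = nn.AdamW([p], lr=0.1, weight_decay=0.5)
    p.grad = np.zeros(4, dtype=np.float32)
    opt.step()
    np.testing.assert_allclose(p.data, 10.0 * (1 - 0.1 * 0.5), rtol=1e-6)


def test_module_state_dict_roundtrip_and_mismatch(rng):
    m = nn.Sequential(nn.Conv2d(2, 3, 3, rng=rng), nn.BatchNorm2d(3))
    sd = m.state_dict()
    m2 = nn.Sequential(nn.Conv2d(2, 3, 3, rng=rng), nn.BatchNorm2d(3))
    m2.load_state_dict(sd)
    x = Tensor(rng.normal(size=(1, 2, 5, 5)).astype(np.float32))
    m.eval(), m2.eval()
    np.testing.assert_array_equal(m(x).data, m2(x).data)
    bad = dict(sd)
    bad.pop(next(iter(sd)))
    with pytest.raises(ValueError):
        m2.load_state_dict(bad)
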