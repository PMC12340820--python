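"""Numba kernels for overdamped Langevin propagation.

The update is Euler–Maruyama for Brownian dynamics:

    x <- x - (dt/gamma) * dU/dx + sqrt(2 kT dt / gamma) * xi

with xi a standard normal. The noise sequence is precomputed outside from a
seeded numpy Generator, so runs are bitwise reproducible for a fixed seed.

Total potential = analytic base + optional harmonic restraint + optional
metadynamics Gaussian bias (hills deposited inside the kernel every
``meta_stride`` steps at the post-step CV value). Hill forces use analytic
Gaussian gradients; hills farther than HILL_CUTOFF standard widths contribute
negligibly and are skipped.
"""

import numpy as np
from numba import njit

# potential kind codes (must match toysim._KIND_CODES)
HARMONIC = 0
DOUBLE_WELL = 1
TILTED_DOUBLE_WELL = 2
HARMONIC_2D = 3
DOUBLE_WELL_2D = 4

HILL_CUTOFF = 6.0


@njit(cache=True)
def grad_1d(code, p, x):
    if code == HARMONIC:
        return p[0] * (x - p[1])
    if code == DOUBLE_WELL:
        x0 = p[1]
        return 4.0 * p[0] * x * (x * x - x0 * x0) / (x0 ** 4)
    if code == TILTED_DOUBLE_WELL:
        x0 = p[1]
        return 4.0 * p[0] * x * (x * x - x0 * x0) / (x0 ** 4) + p[2]
    return 0.0


@njit(cache=True)
def energy_1d(code, p, x):
    if code == HARMONIC:
        d = x - p[1]
        return 0.5 * p[0] * d * d
    if code == DOUBLE_WELL:
        x0 = p[1]
        q = x * x - x0 * x0
        return p[0] * q * q / (x0 ** 4)
    if code == TILTED_DOUBLE_WELL:
        x0 = p[1]
        q = x * x - x0 * x0
        return p[0] * q * q / (x0 ** 4) + p[2] * x
    return 0.0


@njit(cache=True)
def _bias_grad_1d(x, centers, width, height, n_hills):
    """dV_G/dx of the accumulated Gaussian bias."""
    g = 0.0
    w2 = width * width
    cut = HILL_CUTOFF * width
    for j in range(n_hills):
        d = x - centers[j]
        if -cut < d < cut:
            g += -height * d / w2 * np.exp(-0.5 * d * d / w2)
    return g


@njit(cache=True)
def run_1d(
    code,
    p,
    x_init,
    mobility_dt,  # dt/gamma, ps
    noise_scale,  # sqrt(2 kT dt/gamma)
    noise,  # (n_steps,) standard normals
    rest_c,
    rest_k,
    save_every,
    out,  # (n_steps // save_every,) output buffer
    meta_stride,  # 0 disables deposition
    hill_height,
    hill_width,
    hills_c,  # preallocated centers buffer
    hills_step,  # preallocated deposit-step buffer
    n_hills_init,
    bound,
):
    """Propagate one 1D coordinate. Returns (status, x_final, n_hills);
    status 0 on success, or the 1-based step index where |x| exceeded bound."""
    x = x_init
    nh = n_hills_init
    n_steps = noise.shape[0]
    isave = 0
    for step in range(n_steps):
        g = grad_1d(code, p, x)
        if rest_k > 0.0:
            g += rest_k * (x - rest_c)
        if nh > 0:
            g += _bias_grad_1d(x, hills_c, hill_width, hill_height, nh)
        x = x - mobility_dt * g + noise_scale * noise[step]
        if not np.isfinite(x) or (x > bound or x < -bound):
            return step + 1, x, nh
        if meta_stride > 0 and (step + 1) % meta_stride == 0:
            hills_c[nh] = x
            hills_step[nh] = step + 1
            nh += 1
        if (step + 1) % save_every == 0:
            out[isave] = x
            isave += 1
    return 0, x, nh


@njit(cache=True)
def grad_2d(code, p, x, y):
    if code == HARMONIC_2D:
        return p[0] * (x - p[2]), p[1] * (y - p[3])
    if code == DOUBLE_WELL_2D:
        x0 = p[1]
        gx = 4.0 * p[0] * x * (x * x - x0 * x0) / (x0 ** 4) + p[2]
        return gx, p[3] * y
    return 0.0, 0.0


@njit(cache=True)
def energy_2d(code, p, x, y):
    if code == HARMONIC_2D:
        dx = x - p[2]
        dy = y - p[3]
        return 0.5 * p[0] * dx * dx + 0.5 * p[1] * dy * dy
    if code == DOUBLE_WELL_2D:
        x0 = p[1]
        q = x * x - x0 * x0
        return p[0] * q * q / (x0 ** 4) + p[2] * x + 0.5 * p[3] * y * y
    return 0.0


@njit(cache=True)
def _bias_grad_2d(x, y, cx, cy, wx, wy, height, n_hills):
    gx = 0.0
    gy = 0.0
    wx2 = wx * wx
    wy2 = wy * wy
    cutx = HILL_CUTOFF * wx
    cuty = HILL_CUTOFF * wy
    for j in range(n_hills):
        dx = x - cx[j]
        dy = y - cy[j]
        if -cutx < dx < cutx and -cuty < dy < cuty:
            e = height * np.exp(-0.5 * (dx * dx / wx2 + dy * dy / wy2))
            gx += -e * dx / wx2
            gy += -e * dy / wy2
    return gx, gy


@njit(cache=True)
def run_2d(
    code,
    p,
    x_init,
    y_init,
    mobility_dt,
    noise_scale,
    noise,  # (n_steps, 2)
    rest_c0,
    rest_k0,
    rest_c1,
    rest_k1,
    save_every,
    out,  # (n_saved, 2)
    meta_stride,
    hill_height,
    hill_wx,
    hill_wy,
    hills_cx,
    hills_cy,
    hills_step,
    n_hills_init,
    bound,
):
    x = x_init
    y = y_init
    nh = n_hills_init
    n_steps = noise.shape[0]
    isave = 0
    for step in range(n_steps):
        gx, gy = grad_2d(code, p, x, y)
        if rest_k0 > 0.0:
            gx += rest_k0 * (x - rest_c0)
        if rest_k1 > 0.0:
            gy += rest_k1 * (y - rest_c1)
        if nh > 0:
            bx, by = _bias_grad_2d(
                x, y, hills_cx, hills_cy, hill_wx, hill_wy, hill_height, nh
            )
            gx += bx
            gy += by
        x = x - mobility_dt * gx + noise_scale * noise[step, 0]
        y = y - mobility_dt * gy + noise_scale * noise[step, 1]
        if not (np.isfinite(x) and np.isfinite(y)) or max(abs(x), abs(y)) > bound:
            return step + 1, x, y, nh
        if meta_stride > 0 and (step + 1) % meta_stride == 0:
            hills_cx[nh] = x
            hills_cy[nh] = y
            hills_step[nh] = step + 1
            nh += 1
        if (step + 1) % save_every == 0:
            out[isave, 0] = x
            out[isave, 1] = y
            isave += 1
    return 0, x, y, nh
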