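"""Adding-doubling solver for diffuse reflectance of layered turbid slabs.

The solver works in a discrete-ordinates flux convention: reflection and
transmission operators are matrices mapping incident flux per quadrature
channel to outgoing flux per channel, so layer composition is plain matrix
algebra and energy bookkeeping is a column sum.  A homogeneous slab is
grown by repeated doubling from an optically thin starting layer; the
epidermis and dermis stacks are then joined with the adding equations and
wrapped in Fresnel boundary "layers" for the refractive-index mismatch at
the skin surface.

Conventions
-----------
* Quadrature nodes are direction cosines inside the medium.  When the
  relative refractive index exceeds one, the range splits at the critical
  cosine (total internal reflection) and the upper interval uses a Radau
  rule so that mu = 1 is an explicit node; the collimated normal beam
  occupies that channel.
* The phase function is Henyey-Greenstein, expanded in Legendre
  polynomials with delta-M scaling at the quadrature order, and the
  discrete redistribution matrix is symmetrically renormalized so that
  scattering conserves energy exactly on the grid.  A conservative slab
  therefore returns R + T = 1 to floating-point precision.
* "Total diffuse reflectance" excludes the specular component of the
  incident beam, matching a crossed-polarizer measurement.
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np
from numpy.polynomial import legendre as npleg
from scipy.special import roots_jacobi, eval_legendre

from .params import LayerOpticalProperties

__all__ = [
    "adding_doubling_rt",
    "adding_doubling_reflectance",
    "ConfigurationError",
]

_TAU_INIT = 1e-5  # target optical thickness of the doubling seed layer
_MIN_ORDER = 4


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------- quadrature

def _radau_right(n: int):
    """n-point Radau rule on [-1, 1] including the right endpoint x = 1."""
    if n == 1:
        return np.array([1.0]), np.array([2.0])
    interior, _ = roots_jacobi(n - 1, 1, 0)
    x = np.concatenate([np.sort(interior), [1.0]])
    # interpolatory weights in the Legendre basis (exact for the Radau set)
    V = np.stack([eval_legendre(k, x) for k in range(n)])
    m = np.zeros(n)
    m[0] = 2.0
    w = np.linalg.solve(V, m)
    return x, w


def _map_interval(x, w, a, b):
    return a + (b - a) * (x + 1.0) / 2.0, w * (b - a) / 2.0


@lru_cache(maxsize=32)
def _quadrature(order: int, n_rel: float):
    """Direction-cosine nodes and weights inside the medium (ascending)."""
    if order < _MIN_ORDER:
        raise ConfigurationError(f"quadrature order {order} < {_MIN_ORDER}")
    if n_rel > 1.0:
        mu_c = np.sqrt(1.0 - 1.0 / n_rel**2)
        n_lo = order // 2
        n_hi = order - n_lo
        x1, w1 = npleg.leggauss(n_lo)
        mu1, wq1 = _map_interval(x1, w1, 0.0, mu_c)
        x2, w2 = _radau_right(n_hi)
        mu2, wq2 = _map_interval(x2, w2, mu_c, 1.0)
        mu = np.concatenate([mu1, mu2])
        w = np.concatenate([wq1, wq2])
    else:
        x, wq = _radau_right(order)
        mu, w = _map_interval(x, wq, 0.0, 1.0)
    return mu, w


# ------------------------------------------------- phase-function matrices

@lru_cache(maxsize=64)
def _redistribution(order: int, n_rel: float, g: float):
    """Energy-normalized azimuth-averaged HG redistribution matrices.

    Returns (hpp, hpm, scale) where hpp couples co-directed channels,
    hpm couples opposed channels, and ``scale`` = 1 - g**order is the
    delta-M scattering rescaling factor for mus.
    """
    mu, w = _quadrature(order, n_rel)
    N = order
    f = g**N
    ks = np.arange(N)
    chi = (g**ks - f) / (1.0 - f) if f != 1.0 else np.zeros(N)
    P = np.stack([eval_legendre(k, mu) for k in ks])  # (N, M)
    coeff = (2 * ks + 1) * chi
    hpp = np.einsum("k,ki,kj->ij", coeff, P, P)
    sign = (-1.0) ** ks
    hpm = np.einsum("k,ki,kj->ij", coeff * sign, P, P)
    # Symmetric renormalization so that discrete scattering conserves
    # energy: 0.5 * sum_i w_i (hpp + hpm)[i, j] == 1 for every j.
    d = np.ones_like(mu)
    for _ in range(100):
        col = 0.5 * ((w * d) @ (hpp * d) + (w * d) @ (hpm * d))
        if np.max(np.abs(col - 1.0)) < 1e-13:
            break
        d = d / np.sqrt(np.abs(col))
    hpp = hpp * d[:, None] * d[None, :]
    hpm = hpm * d[:, None] * d[None, :]
    return hpp, hpm, 1.0 - f


# ------------------------------------------------------------ slab doubling

def _slab_rt(mua, mus, g, d, order, n_rel):
    """R, T flux matrices of a homogeneous slab, batched over leading dims.

    mua, mus : arrays broadcastable to a common shape (...,); g scalar.
    Returns arrays of shape (..., M, M).
    """
    mu, w = _quadrature(order, n_rel)
    hpp, hpm, dm_scale = _redistribution(order, n_rel, float(g))
    M = mu.size

    mua = np.asarray(mua, float)
    mus_s = np.asarray(mus, float) * dm_scale  # delta-M scaled scattering
    mut = mua + mus_s
    tau = mut * d
    albedo = np.where(mut > 0, mus_s / np.where(mut > 0, mut, 1.0), 0.0)

    tau_max = float(np.max(tau)) if tau.size else 0.0
    if tau_max <= _TAU_INIT:
        k_dbl = 0
    else:
        k_dbl = int(np.ceil(np.log2(tau_max / _TAU_INIT)))
    dtau = tau / 2**k_dbl

    # thin-layer initialization (exactly flux-conserving for albedo = 1)
    surv = np.exp(-dtau[..., None] / mu)                    # (..., M)
    p_int = -np.expm1(-dtau[..., None] / mu)                # 1 - exp(-dtau/mu)
    scat = albedo[..., None] * p_int                        # (..., M)
    wi = w[:, None] * np.ones((M, M))
    T = 0.5 * scat[..., None, :] * hpp * wi
    R = 0.5 * scat[..., None, :] * hpm * wi
    idx = np.arange(M)
    T[..., idx, idx] += surv

    eye = np.eye(M)
    for _ in range(k_dbl):
        G = np.linalg.solve(eye - R @ R, T)
        R = R + T @ R @ G
        T = T @ G
    return R, T


def _fresnel_inside(mu, n_rel):
    """Unpolarized Fresnel reflectance for light inside the medium hitting
    the surface at direction cosine mu (relative index n_rel = n_in/n_out)."""
    mu = np.asarray(mu, float)
    sin_i2 = 1.0 - mu**2
    sin_t2 = n_rel**2 * sin_i2
    r = np.ones_like(mu)
    ok = sin_t2 < 1.0
    cos_t = np.sqrt(np.clip(1.0 - sin_t2[ok], 0.0, None))
    cos_i = mu[ok]
    rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
    rp = (n_rel * cos_t - cos_i) / (n_rel * cos_t + cos_i)
    r[ok] = 0.5 * (rs**2 + rp**2)
    return r


def _combine(R1, T1, R2, T2):
    """Add layer 2 below layer 1 (both internally symmetric).

    Returns (R_top, T_down) of the stack for light incident from above.
    """
    eye = np.eye(R1.shape[-1])
    G = np.linalg.solve(eye - R1 @ R2, T1)
    R = R1 + T1 @ R2 @ G
    T = T2 @ G
    return R, T


def adding_doubling_rt(layers, quadrature_order: int = 16,
                       n_ambient: float = 1.0):
    """Total diffuse reflectance and transmittance of a layer stack.

    Parameters
    ----------
    layers : sequence of LayerOpticalProperties, top first.  All layers
        must share the refractive index (internal interfaces are index
        matched); the external mismatch sits at the top and bottom
        surfaces.  Illumination is a collimated, normally incident beam;
        the specular reflection is excluded from R.
    quadrature_order : number of direction-cosine nodes (>= 4).

    Returns
    -------
    (R, T) : arrays over the layers' wavelength axis, each in [0, 1].
    """
    if len(layers) < 1:
        raise ValueError("at least one layer is required")
    if quadrature_order < _MIN_ORDER:
        raise ConfigurationError(
            f"quadrature order must be >= {_MIN_ORDER}, got {quadrature_order}")
    n_med = layers[0].n
    if any(abs(l.n - n_med) > 1e-12 for l in layers):
        raise ValueError("all layers must share a refractive index")
    n_rel = n_med / n_ambient
    mu, w = _quadrature(quadrature_order, round(n_rel, 12))
    M = mu.size

    R = T = None
    for lay in layers:
        Rl, Tl = _slab_rt(lay.mua, lay.mus, lay.g, lay.d,
                          quadrature_order, round(n_rel, 12))
        if R is None:
            R, T = Rl, Tl
        else:
            R, T = _combine(R, T, Rl, Tl)

    beam = M - 1  # the mu = 1 Radau node carries the collimated beam
    if n_rel > 1.0:
        rF = _fresnel_inside(mu, n_rel)
        r_spec = ((n_rel - 1.0) / (n_rel + 1.0)) ** 2
        Rb = np.diag(rF)
        # slab + bottom boundary (transmitted flux leaves to the collector)
        R, T = _combine(R, T, Rb, np.diag(1.0 - rF))
        # top-boundary interreflection of the upward flux inside the slab
        eye = np.eye(M)
        d0 = np.zeros(M)
        d0[beam] = 1.0 - r_spec
        u0 = np.einsum("...ij,j->...i", R, d0)
        u = np.linalg.solve(eye - R @ Rb, u0[..., None])[..., 0]
        Rtot = np.einsum("i,...i->...", 1.0 - rF, u)
        dtop = d0 + np.einsum("ij,...j->...i", Rb, u)
        Ttot = np.einsum("...ij,...j->...i", T, dtop).sum(axis=-1)
    else:
        Rtot = R[..., :, beam].sum(axis=-1)
        Ttot = T[..., :, beam].sum(axis=-1)
    return Rtot, Ttot


def adding_doubling_reflectance(layers, quadrature_order: int = 16,
                                n_ambient: float = 1.0):
    """Total diffuse reflectance of the stack (see adding_doubling_rt)."""
    return adding_doubling_rt(layers, quadrature_order, n_ambient)[0]
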