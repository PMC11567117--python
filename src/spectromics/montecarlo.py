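"""Photon-transport Monte Carlo reference for layered slabs.

An independent oracle for the adding-doubling solver: weighted photon
packets with Henyey-Greenstein scattering, implicit capture, Russian
roulette and Fresnel boundaries, in the style of the classic multilayer
MCML scheme.  All layers must share a refractive index; the mismatch sits
at the external surfaces.  The collimated beam enters normally and the
specular reflection is excluded, matching the adding-doubling convention.
"""
from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["mc_reference_reflectance", "MCResult"]

_W_ROULETTE = 1e-4
_ROULETTE_P = 0.1


@njit(cache=True)
def _run(z_bounds, mua, mus, g, n_rel, n_photons, seed, n_batches):
    np.random.seed(seed)
    n_layers = mua.shape[0]
    z_top = 0.0
    z_bot = z_bounds[n_layers]
    r_spec = ((n_rel - 1.0) / (n_rel + 1.0)) ** 2 if n_rel != 1.0 else 0.0
    batch_R = np.zeros(n_batches)
    batch_T = np.zeros(n_batches)
    per_batch = n_photons // n_batches

    for b in range(n_batches):
        acc_R = 0.0
        acc_T = 0.0
        for _ in range(per_batch):
            z = 0.0
            ux, uy, uz = 0.0, 0.0, 1.0
            w = 1.0 - r_spec
            layer = 0
            alive = True
            while alive:
                mut = mua[layer] + mus[layer]
                if mut <= 0.0:
                    # ballistic through a void layer
                    if uz > 0.0:
                        z = z_bounds[layer + 1]
                        layer += 1
                    elif uz < 0.0:
                        z = z_bounds[layer]
                        layer -= 1
                    else:
                        alive = False
                        continue
                else:
                    tau = -math.log(np.random.random())
                    s = tau / mut
                    # propagate, handling layer/surface crossings
                    while True:
                        if uz > 0.0:
                            db = (z_bounds[layer + 1] - z) / uz
                        elif uz < 0.0:
                            db = (z_bounds[layer] - z) / uz
                        else:
                            db = 1e30
                        if s < db:
                            z += s * uz
                            break
                        # reach the boundary
                        s -= db
                        z += db * uz
                        going_down = uz > 0.0
                        at_external = (going_down and layer == n_layers - 1) or \
                                      (not going_down and layer == 0)
                        if not at_external:
                            layer += 1 if going_down else -1
                            nmut = mua[layer] + mus[layer]
                            if nmut <= 0.0:
                                # skip void interior layer ballistically
                                continue
                            s = s * mut / nmut
                            mut = nmut
                            continue
                        # external surface: Fresnel
                        ci = abs(uz)
                        if n_rel == 1.0:
                            refl = 0.0
                        else:
                            sin_t2 = n_rel * n_rel * (1.0 - ci * ci)
                            if sin_t2 >= 1.0:
                                refl = 1.0
                            else:
                                ct = math.sqrt(1.0 - sin_t2)
                                rs = (n_rel * ci - ct) / (n_rel * ci + ct)
                                rp = (n_rel * ct - ci) / (n_rel * ct + ci)
                                refl = 0.5 * (rs * rs + rp * rp)
                        if np.random.random() > refl:
                            if going_down:
                                acc_T += w
                            else:
                                acc_R += w
                            alive = False
                            break
                        uz = -uz
                    if not alive:
                        break
                    # interaction: implicit capture + HG scatter
                    w *= mus[layer] / mut
                    if w < _W_ROULETTE:
                        if np.random.random() < _ROULETTE_P:
                            w /= _ROULETTE_P
                        else:
                            alive = False
                            continue
                    gg = g[layer]
                    if gg != 0.0:
                        tmp = (1.0 - gg * gg) / (1.0 - gg + 2.0 * gg * np.random.random())
                        ct = (1.0 + gg * gg - tmp * tmp) / (2.0 * gg)
                    else:
                        ct = 2.0 * np.random.random() - 1.0
                    if ct > 1.0:
                        ct = 1.0
                    elif ct < -1.0:
                        ct = -1.0
                    st = math.sqrt(1.0 - ct * ct)
                    phi = 2.0 * math.pi * np.random.random()
                    cp = math.cos(phi)
                    sp = math.sin(phi)
                    if abs(uz) > 0.99999:
                        ux = st * cp
                        uy = st * sp
                        uz = ct * (1.0 if uz >= 0.0 else -1.0)
                    else:
                        den = math.sqrt(1.0 - uz * uz)
                        nux = st * (ux * uz * cp - uy * sp) / den + ux * ct
                        nuy = st * (uy * uz * cp + ux * sp) / den + uy * ct
                        nuz = -st * cp * den + uz * ct
                        ux, uy, uz = nux, nuy, nuz
        batch_R[b] = acc_R / per_batch
        batch_T[b] = acc_T / per_batch
    return batch_R, batch_T


class MCResult:
    """Reflectance/transmittance estimate with standard errors."""

    def __init__(self, reflectance, transmittance, se_reflectance,
                 se_transmittance, n_photons):
        self.reflectance = reflectance
        self.transmittance = transmittance
        self.se_reflectance = se_reflectance
        self.se_transmittance = se_transmittance
        self.n_photons = n_photons


def mc_reference_reflectance(layers, n_photons: int = 10**5,
                             seed: int = 0, n_ambient: float = 1.0,
                             n_batches: int = 10) -> MCResult:
    """Monte-Carlo total diffuse reflectance of a layer stack.

    Parameters mirror :func:`adding_doubling_rt`; each layer's mua/musp
    must be scalar (one wavelength).  Seeded and reproducible: identical
    inputs and seed give identical output.
    """
    if n_photons < 10**4:
        raise ValueError("use at least 1e4 photons for a meaningful estimate")
    mua = np.array([float(np.squeeze(l.mua)) for l in layers])
    mus = np.array([float(np.squeeze(l.mus)) for l in layers])
    g = np.array([l.g for l in layers])
    n_med = layers[0].n
    if any(abs(l.n - n_med) > 1e-12 for l in layers):
        raise ValueError("all layers must share a refractive index")
    d = np.array([l.d for l in layers])
    z_bounds = np.concatenate([[0.0], np.cumsum(d)])
    bR, bT = _run(z_bounds, mua, mus, g, n_med / n_ambient,
                  int(n_photons), int(seed), int(n_batches))
    return MCResult(
        reflectance=float(bR.mean()),
        transmittance=float(bT.mean()),
        se_reflectance=float(bR.std(ddof=1) / math.sqrt(n_batches)),
        se_transmittance=float(bT.std(ddof=1) / math.sqrt(n_batches)),
        n_photons=int(n_photons),
    )
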