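"""Radial finite-difference solver for the porous-medium diffusion equation.

Independent numerical cross-check for the closed-form point-source model in
:mod:`ecsastro.rti_model`.  It integrates

    ∂C/∂t = (D/λ²) ∇²C − k′ C + q(r)/α

in spherical symmetry, with the source distributed uniformly over a small
ball of radius ``src_radius`` (total release Q mol/s).  Outside that ball
the field converges to the ideal point-source solution as the ball
shrinks.  The substitution u = r·C turns the radial Laplacian into a plain
second derivative, and the system is advanced by Crank–Nicolson on a
uniform grid with u(0) = 0 and u(r_max) = 0.

This module is used only for validation; the fitting pipeline never calls
it.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_banded

from .rti_model import DiffusionParams

__all__ = ["solve_point_source_on"]


def solve_point_source_on(
    p: DiffusionParams,
    Q: float,
    r_eval,
    t_eval,
    *,
    r_max: float = 0.12,
    n_r: int = 6000,
    dt: float = 0.005,
    src_radius: float = 1e-4,
) -> np.ndarray:
    """Concentration increment C(r_eval, t_eval) for a source on since t=0.

    Parameters
    ----------
    p, Q : model parameters and molar release rate (mol/s).
    r_eval : radii, cm (must lie well inside ``r_max``).
    t_eval : sorted times, s.
    r_max, n_r, dt : domain size (cm), grid points, time step (s).
    src_radius : radius of the uniform source ball, cm (default 1 µm).

    Returns array of shape ``(len(t_eval), len(r_eval))`` in mol/cm³.
    """
    r_eval = np.atleast_1d(np.asarray(r_eval, dtype=float))
    t_eval = np.atleast_1d(np.asarray(t_eval, dtype=float))
    if np.any(np.diff(t_eval) <= 0) or t_eval[0] < 0:
        raise ValueError("t_eval must be sorted, nonnegative")
    if np.max(r_eval) > 0.5 * r_max:
        raise ValueError("r_eval too close to the outer boundary")

    D_app = p.D / p.lam**2
    k = p.kprime
    r = np.linspace(0.0, r_max, n_r + 1)
    dr = r[1] - r[0]
    interior = slice(1, n_r)  # u fixed to 0 at both ends
    n_int = n_r - 1

    # volumetric source density inside the ball, scaled by 1/alpha
    v_src = 4.0 / 3.0 * np.pi * src_radius**3
    q = np.where(r <= src_radius, Q / (v_src * p.alpha), 0.0)
    s_int = (r * q)[interior]  # source term for u = r*C
    # conservative normalisation: the exterior field is set by ∫ρ·s(ρ)dρ,
    # whose node-sampled sum overweights the ball edge; rescale so the
    # discrete total release equals Q exactly.
    discrete = np.sum(r[interior] * s_int) * dr
    exact = q.max() * src_radius**3 / 3.0
    if discrete > 0:
        s_int *= exact / discrete

    # Crank–Nicolson matrices for u_t = D_app u_rr - k u + s
    mu = D_app * dt / (2.0 * dr**2)
    kappa = k * dt / 2.0
    # LHS: (1 + 2mu + kappa) on diag, -mu off; RHS mirrored
    ab = np.zeros((3, n_int))
    ab[0, 1:] = -mu
    ab[1, :] = 1.0 + 2.0 * mu + kappa
    ab[2, :-1] = -mu

    u = np.zeros(n_int)
    out = np.zeros((len(t_eval), len(r_eval)))
    t = 0.0
    next_idx = 0
    # emit any t_eval == 0
    while next_idx < len(t_eval) and t_eval[next_idx] <= 1e-12:
        next_idx += 1

    def _emit(idx: int, u_prev, u_curr, t_prev, t_curr):
        # linear interpolation in time, then in radius
        w = 0.0 if t_curr == t_prev else (t_eval[idx] - t_prev) / (t_curr - t_prev)
        u_t = (1 - w) * u_prev + w * u_curr
        u_full = np.concatenate(([0.0], u_t, [0.0]))
        c_full = np.zeros_like(u_full)
        c_full[1:] = u_full[1:] / r[1:]
        c_full[0] = c_full[1]
        out[idx] = np.interp(r_eval, r, c_full)

    t_end = t_eval[-1]
    while t < t_end - 1e-12:
        step = min(dt, t_end - t)
        if step != dt:
            mu_s = D_app * step / (2.0 * dr**2)
            kap_s = k * step / 2.0
            ab_s = np.zeros((3, n_int))
            ab_s[0, 1:] = -mu_s
            ab_s[1, :] = 1.0 + 2.0 * mu_s + kap_s
            ab_s[2, :-1] = -mu_s
        else:
            mu_s, kap_s, ab_s = mu, kappa, ab
        rhs = (1.0 - 2.0 * mu_s - kap_s) * u
        rhs[1:] += mu_s * u[:-1]
        rhs[:-1] += mu_s * u[1:]
        rhs += step * s_int
        u_new = solve_banded((1, 1), ab_s, rhs)
        t_new = t + step
        while next_idx < len(t_eval) and t_eval[next_idx] <= t_new + 1e-12:
            _emit(next_idx, u, u_new, t, t_new)
            next_idx += 1
        u, t = u_new, t_new

    return out
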