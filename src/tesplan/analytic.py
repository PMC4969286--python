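"""Quasi-static potentials in concentric multi-shell spheres (Legendre series).

This is the analytic oracle used to validate the finite-difference forward
solver: for a layered sphere with piecewise-constant isotropic conductivity
the potential separates into Legendre harmonics, and per degree ``n`` the
radial coefficients in each shell follow from continuity of potential and
radial current at the interfaces plus the insulating outer boundary — a
small linear system solved here directly, with per-shell scaled basis
functions so the system stays well conditioned at high degree.

Three source types are supported:

* :class:`DipoleSource` — an ideal current dipole inside the innermost
  shell (the classical EEG forward model);
* :class:`MonopoleSource` — a zero-sum set of point current sources inside
  one shell, which can be placed exactly at the discrete source voxels of a
  finite-difference solve (the degree-0 harmonic has the closed form
  ``sum_s I_s / (4 pi sigma max(r, b_s))``);
* :class:`InjectionSource` — point currents exactly on the outer surface,
  entering through the boundary-flux expansion.  On-surface sources make
  the series only conditionally convergent at other surface points, so
  prefer :class:`MonopoleSource` slightly below the surface when accuracy
  at the surface matters.

Conventions: SI units internally (meters, amperes, A·m, volts); the public
API takes millimeters.  Associated Legendre functions use the
Condon–Shortley phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from tesplan.phantom import ConductivityTable, DEFAULT_CONDUCTIVITIES, ShellSpec

__all__ = ["DipoleSource", "MonopoleSource", "InjectionSource", "analytic_shell_potential"]

_MM = 1e-3


@dataclass(frozen=True)
class DipoleSource:
    """Current dipole inside the innermost shell: position (mm), moment (A·m)."""

    position_mm: tuple[float, float, float]
    moment: tuple[float, float, float]


@dataclass(frozen=True)
class MonopoleSource:
    """Zero-sum point currents (A) at interior positions (mm), all in one shell."""

    points_mm: np.ndarray
    currents_a: np.ndarray


@dataclass(frozen=True)
class InjectionSource:
    """Point currents on the outer surface; currents (A) must sum to zero."""

    points_mm: np.ndarray
    currents_a: np.ndarray


def _legendre_pair(x: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """P_n(x) and P_n^1(x) for n = 0..order, stacked (order+1, len(x))."""
    x = np.asarray(x, dtype=float)
    P = np.zeros((order + 1, x.size))
    P1 = np.zeros((order + 1, x.size))
    P[0] = 1.0
    if order >= 1:
        P[1] = x
        P1[1] = -np.sqrt(np.clip(1.0 - x**2, 0.0, None))
    for n in range(1, order):
        P[n + 1] = ((2 * n + 1) * x * P[n] - n * P[n - 1]) / (n + 1)
        P1[n + 1] = ((2 * n + 1) * x * P1[n] - (n + 1) * P1[n - 1]) / n
    return P, P1


class _ShellSolver:
    """Per-degree coefficient solver for one layered sphere and one source."""

    def __init__(self, radii_m: np.ndarray, sigmas: np.ndarray, src_region: int):
        self.radii = radii_m
        self.sigmas = sigmas
        self.k = src_region  # 1-based shell index containing the source (0: boundary source)
        self.L = len(radii_m)

    def solve(self, n: int, src_val, src_dval, outer_flux: float) -> np.ndarray:
        """Coefficients [a_1, a_2, b_2, ..., a_L, b_L] for degree n >= 1.

        ``src_val(r)`` / ``src_dval(r)`` give the source singular term and
        its radial derivative at radius r (the caller supplies the branch
        valid on the relevant side of the source radius); they are added on
        the source shell's side of each interface equation.
        """
        L, radii, sigmas, k = self.L, self.radii, self.sigmas, self.k
        m = 2 * L - 1
        A = np.zeros((m, m))
        rhs = np.zeros(m)

        def col_a(j: int) -> int:
            return 0 if j == 1 else 2 * j - 3

        def col_b(j: int) -> int:
            return 2 * j - 2

        row = 0
        for i in range(1, L):  # interface between shell i and i+1 at radii[i-1]
            r = radii[i - 1]
            A[row, col_a(i)] = 1.0
            if i > 1:
                A[row, col_b(i)] = (radii[i - 2] / r) ** (n + 1)
            A[row, col_a(i + 1)] = -((r / radii[i]) ** n)
            A[row, col_b(i + 1)] = -1.0
            if k == i:
                rhs[row] = -src_val(r)
            elif k == i + 1:
                rhs[row] = src_val(r)
            row += 1
            A[row, col_a(i)] = sigmas[i - 1] * n / r
            if i > 1:
                A[row, col_b(i)] = -sigmas[i - 1] * (n + 1) / r * (radii[i - 2] / r) ** (n + 1)
            A[row, col_a(i + 1)] = -sigmas[i] * n / r * (r / radii[i]) ** n
            A[row, col_b(i + 1)] = sigmas[i] * (n + 1) / r
            if k == i:
                rhs[row] = -sigmas[i - 1] * src_dval(r)
            elif k == i + 1:
                rhs[row] = sigmas[i] * src_dval(r)
            row += 1

        R = radii[-1]
        A[row, col_a(L)] = sigmas[-1] * n / R
        if L > 1:
            A[row, col_b(L)] = -sigmas[-1] * (n + 1) / R * (radii[-2] / R) ** (n + 1)
        rhs[row] = outer_flux
        if k == L:
            rhs[row] -= sigmas[-1] * src_dval(R)
        return np.linalg.solve(A, rhs)

    def eval_radial(self, coeffs: np.ndarray, r: float, n: int, src_val) -> float:
        """Degree-n radial factor at radius r, source term included in its shell."""
        radii, L, k = self.radii, self.L, self.k
        j = min(int(np.searchsorted(radii, r * (1 - 1e-12))) + 1, L)
        if j == 1:
            val = coeffs[0] * (r / radii[0]) ** n
        else:
            val = coeffs[2 * j - 3] * (r / radii[j - 1]) ** n + coeffs[2 * j - 2] * (
                radii[j - 2] / r
            ) ** (n + 1)
        if j == k and src_val is not None:
            val += src_val(r)
        return val


def _shell_of(radii_m: np.ndarray, r: float) -> int:
    return min(int(np.searchsorted(radii_m, r * (1 - 1e-12))) + 1, len(radii_m))


def _axis_frame(position: np.ndarray, moment: np.ndarray):
    b = float(np.linalg.norm(position))
    if b < 1e-12:
        p_norm = float(np.linalg.norm(moment))
        u = moment / p_norm if p_norm > 0 else np.array([0.0, 0.0, 1.0])
        return u, p_norm, 0.0, np.zeros(3)
    u = position / b
    p_r = float(moment @ u)
    tan = moment - p_r * u
    p_t = float(np.linalg.norm(tan))
    t_hat = tan / p_t if p_t > 1e-15 * max(1.0, abs(p_r)) else np.zeros(3)
    return u, p_r, p_t if t_hat.any() else 0.0, t_hat


def analytic_shell_potential(
    spec: ShellSpec,
    source: DipoleSource | MonopoleSource | InjectionSource,
    observation_points_mm: np.ndarray,
    table: ConductivityTable = DEFAULT_CONDUCTIVITIES,
    max_order: int = 100,
    tol: float = 1e-8,
    average_reference: bool = True,
) -> np.ndarray:
    """Series potential (V) of a layered-sphere conductor at observation points.

    Coordinates are interpreted relative to the shell center
    (``spec.center_mm`` or the origin); observation points may lie anywhere
    inside or on the outer surface.  The series is truncated at
    ``max_order`` or earlier once the largest per-degree contribution falls
    below ``tol`` times the running solution norm.
    """
    center = np.asarray(spec.center_mm if spec.center_mm is not None else (0.0, 0.0, 0.0))
    radii_m = np.asarray(spec.radii_mm, dtype=float) * _MM
    sigmas = np.array([table[t] for t in spec.tissues], dtype=float)
    if np.any(sigmas <= 0):
        raise ValueError("all shell conductivities must be positive")
    R = radii_m[-1]

    obs = (np.atleast_2d(np.asarray(observation_points_mm, dtype=float)) - center) * _MM
    obs_r = np.linalg.norm(obs, axis=1)
    if np.any(obs_r > R * (1 + 1e-9)):
        raise ValueError("observation points must lie inside or on the outer surface")
    obs_r = np.minimum(obs_r, R)
    obs_unit = obs / np.where(obs_r[:, None] > 0, obs_r[:, None], 1.0)

    phi = np.zeros(obs.shape[0])

    if isinstance(source, DipoleSource):
        pos = (np.asarray(source.position_mm, dtype=float) - center) * _MM
        b = float(np.linalg.norm(pos))
        if b >= radii_m[0]:
            raise ValueError("dipole must lie strictly inside the innermost shell")
        u, p_r, p_t, t_hat = _axis_frame(pos, np.asarray(source.moment, dtype=float))
        x = obs_unit @ u
        P, P1 = _legendre_pair(x, max_order)
        if p_t > 0:
            w = obs_unit - x[:, None] * u
            wn = np.linalg.norm(w, axis=1)
            cos_az = np.where(wn > 1e-15, (w @ t_hat) / np.where(wn > 0, wn, 1.0), 0.0)
        solver = _ShellSolver(radii_m, sigmas, src_region=1)
        four_pi_sigma = 4.0 * np.pi * sigmas[0]
        for n in range(1, max_order + 1):
            term = np.zeros_like(phi)

            def ratio(r: float) -> float:
                if b == 0.0:
                    return 1.0 if n == 1 else 0.0
                return (b / r) ** (n - 1)

            for c, ang in (
                (n * p_r / four_pi_sigma, P[n]),
                ((-p_t / four_pi_sigma, P1[n] * cos_az) if p_t > 0 else (0.0, None)),
            ):
                if c == 0.0:
                    continue
                sv = lambda r, c=c: c * ratio(r) / r**2
                sdv = lambda r, c=c: -(n + 1) / r * c * ratio(r) / r**2
                coeffs = solver.solve(n, sv, sdv, 0.0)
                rad = np.array([solver.eval_radial(coeffs, r, n, sv) for r in obs_r])
                term += rad * ang
            phi += term
            scale = np.max(np.abs(phi))
            if scale > 0 and np.max(np.abs(term)) < tol * scale and n > 2:
                break

    elif isinstance(source, MonopoleSource):
        pts = (np.atleast_2d(np.asarray(source.points_mm, dtype=float)) - center) * _MM
        cur = np.asarray(source.currents_a, dtype=float)
        if abs(cur.sum()) > 1e-12 * max(1.0, np.max(np.abs(cur))):
            raise ValueError("monopole currents must sum to zero")
        b_all = np.linalg.norm(pts, axis=1)
        regions = {_shell_of(radii_m, b) for b in b_all}
        if len(regions) != 1:
            raise ValueError("all monopoles must lie within the same shell")
        k = regions.pop()
        sigma_k = sigmas[k - 1]
        # exact degree-0 harmonic: I / (4 pi sigma max(r, b)) summed over sources
        for b, I in zip(b_all, cur):
            phi += I / (4.0 * np.pi * sigma_k * np.maximum(obs_r, b))
        solver = _ShellSolver(radii_m, sigmas, src_region=k)
        for b, I, pt in zip(b_all, cur, pts):
            if I == 0.0:
                continue
            axis = pt / b if b > 0 else np.array([0.0, 0.0, 1.0])
            x = obs_unit @ axis
            P, _ = _legendre_pair(x, max_order)
            C = I / (4.0 * np.pi * sigma_k)
            contrib = np.zeros_like(phi)
            for n in range(1, max_order + 1):
                # exterior branch (r > b) at interfaces above, interior below
                out_v = lambda r: C * (b / r) ** n / r
                out_d = lambda r: -(n + 1) / r * C * (b / r) ** n / r
                in_v = lambda r: C * (r / b) ** n / b if b > 0 else 0.0
                in_d = lambda r: n / r * (C * (r / b) ** n / b) if b > 0 else 0.0

                def branch_val(r: float, b=b, out_v=out_v, in_v=in_v) -> float:
                    return out_v(r) if r >= b else in_v(r)

                def branch_dval(r: float, b=b, out_d=out_d, in_d=in_d) -> float:
                    return out_d(r) if r >= b else in_d(r)

                coeffs = solver.solve(n, branch_val, branch_dval, 0.0)
                rad = np.array([solver.eval_radial(coeffs, r, n, branch_val) for r in obs_r])
                term = rad * P[n]
                contrib += term
                scale = max(np.max(np.abs(contrib)), np.max(np.abs(phi)))
                if scale > 0 and np.max(np.abs(term)) < tol * scale and n > 2:
                    break
            phi += contrib

    elif isinstance(source, InjectionSource):
        pts = (np.atleast_2d(np.asarray(source.points_mm, dtype=float)) - center) * _MM
        cur = np.asarray(source.currents_a, dtype=float)
        if abs(cur.sum()) > 1e-12 * max(1.0, np.max(np.abs(cur))):
            raise ValueError("injection currents must sum to zero")
        pr = np.linalg.norm(pts, axis=1)
        if np.any(np.abs(pr - R) > 1e-3 * R):
            raise ValueError("injection points must lie on the outer surface")
        solver = _ShellSolver(radii_m, sigmas, src_region=0)
        for axis, I in zip(pts / pr[:, None], cur):
            if I == 0.0:
                continue
            x = obs_unit @ axis
            P, _ = _legendre_pair(x, max_order)
            contrib = np.zeros_like(phi)
            for n in range(1, max_order + 1):
                g = I * (2 * n + 1) / (4.0 * np.pi * R**2)
                coeffs = solver.solve(n, lambda r: 0.0, lambda r: 0.0, g)
                rad = np.array([solver.eval_radial(coeffs, r, n, None) for r in obs_r])
                term = rad * P[n]
                contrib += term
                scale = np.max(np.abs(contrib))
                if scale > 0 and np.max(np.abs(term)) < tol * scale and n > 2:
                    break
            phi += contrib
    else:
        raise TypeError(f"unsupported source type {type(source).__name__}")

    if average_reference:
        phi = phi - phi.mean()
    return phi
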