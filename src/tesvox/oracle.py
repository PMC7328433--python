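"""Analytic voltage and electric field for an N-layer concentric sphere.

A point current source and sink on the outer surface of a sphere of
concentric, piecewise-homogeneous shells admit a Legendre-series solution

    V_j(r, γ) = Σ_n [ A_jn (r/r_j)^n + B_jn (r/r_j)^-(n+1) ] P_n(cos γ),

one expansion per shell j, with coefficients fixed by continuity of V and of
the radial current density σ ∂V/∂r across shell boundaries, regularity at the
center, and the Neumann point-current condition at the outer surface.  The
source/sink pair is superposed, which cancels the monopole (n = 0) term.
This is the standard ground truth for validating volume-conduction solvers.

Numerics
--------
* Coefficients are propagated shell-to-shell as a 2x2 solve per harmonic in a
  radius-normalized basis (each shell's own outer radius), which keeps the
  recursion well-scaled for head-like geometries.
* In the outer shell the raw series converges slowly near the surface, so the
  large-n limit — the closed-form homogeneous-sphere point-source potential
  with the outer shell's conductivity — is summed in closed form and only the
  (geometrically decaying) difference series is truncated.
* Fields are obtained by term-wise differentiation; the apparent 1/sin γ in
  the tangential component cancels analytically, so on-axis points are exact.

Point electrodes (delta currents) are used rather than finite discs: the
series is then exact, and FEM comparisons simply exclude a cap around each
electrode where the point/disc mismatch dominates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, EvaluationError


@dataclass
class SphereModel:
    """Concentric-shell sphere with a surface point source and sink.

    radii_mm are ascending shell outer radii (innermost first); sigmas_S_per_m
    are the matching conductivities.  source/sink are unit direction vectors
    from the center to the surface electrodes; current_mA flows in at the
    source and out at the sink.
    """

    radii_mm: tuple[float, ...]
    sigmas_S_per_m: tuple[float, ...]
    source: tuple[float, float, float] = (0.0, 0.0, 1.0)
    sink: tuple[float, float, float] = (0.0, 0.0, -1.0)
    current_mA: float = 1.0
    n_terms: int = 300
    _coef: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        radii = np.asarray(self.radii_mm, dtype=float)
        sig = np.asarray(self.sigmas_S_per_m, dtype=float)
        if len(radii) != len(sig):
            raise ConfigurationError("one conductivity per shell required")
        if np.any(np.diff(radii) <= 0) or radii[0] <= 0:
            raise ConfigurationError("radii must be positive and ascending")
        if np.any(sig <= 0):
            raise ConfigurationError("conductivities must be positive")
        if self.n_terms < 1:
            raise ConfigurationError("n_terms must be >= 1")
        for name in ("source", "sink"):
            v = np.asarray(getattr(self, name), dtype=float)
            if abs(np.linalg.norm(v) - 1.0) > 1e-8:
                raise ConfigurationError(f"{name} must be a unit vector")

    # ---- coefficients ----------------------------------------------------
    def _coefficients(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(A, B, alpha_h): per-shell coefficient tables (n_shells, n_terms)
        for unit basis functions normalized by each shell's outer radius, in
        volts for the model's current, plus the homogeneous-outer reference
        coefficients used for series acceleration.  Cached."""
        key = self.n_terms
        if key in self._coef:
            return self._coef[key]
        radii = np.asarray(self.radii_mm, dtype=float) / 1000.0  # m
        sig = np.asarray(self.sigmas_S_per_m, dtype=float)
        N = len(radii)
        R = radii[-1]
        I = self.current_mA * 1e-3
        ns = np.arange(1, self.n_terms + 1, dtype=float)
        A = np.zeros((N, self.n_terms))
        B = np.zeros((N, self.n_terms))
        A[0] = 1.0
        for j in range(N - 1):
            x = radii[j] / radii[j + 1]
            p = x**ns
            q = x ** -(ns + 1)
            val = A[j] + B[j]
            flux = sig[j] * (ns * A[j] - (ns + 1) * B[j])
            sp1 = sig[j + 1]
            A[j + 1] = (sp1 * (ns + 1) * val + flux) / (sp1 * p * (2 * ns + 1))
            B[j + 1] = (sp1 * ns * val - flux) / (sp1 * q * (2 * ns + 1))
            peak = np.maximum(np.abs(A[j + 1]), np.abs(B[j + 1]))
            big = peak > 1e200
            if big.any():  # rescale the whole column; overall scale is free
                A[:, big] /= peak[big]
                B[:, big] /= peak[big]
        # Neumann surface condition: sigma_N dV/dr(R) = I (2n+1) / (4 pi R^2)
        denom = sig[-1] * (ns * A[-1] - (ns + 1) * B[-1])
        scale = I * (2 * ns + 1) / (4 * np.pi * R * denom)
        A *= scale
        B *= scale
        alpha_h = I * (2 * ns + 1) / (4 * np.pi * sig[-1] * ns * R)
        out = (A, B, alpha_h)
        self._coef[key] = out
        return out

    # ---- public API ------------------------------------------------------
    def voltage(self, points_mm: np.ndarray, demean: bool = True) -> np.ndarray:
        """Voltage (V) at world points (mm), zero-mean over the point set."""
        V, _ = self._evaluate(points_mm, want_field=False)
        if demean:
            V = V - V.mean()
        return V

    def field(self, points_mm: np.ndarray) -> np.ndarray:
        """E = -∇V (V/m, Cartesian components) at world points (mm)."""
        _, E = self._evaluate(points_mm, want_field=True)
        return E

    def tail_estimate(self, points_mm: np.ndarray) -> float:
        """Magnitude of the last retained series term, maximized over points —
        a truncation-error indicator."""
        return float(self._evaluate(points_mm, want_field=False, tail=True)[0][0])

    # ---- evaluation core -------------------------------------------------
    #: points per evaluation block; the per-point working set is
    #: O(n_terms) floats, so blocks bound peak memory for large point sets
    _CHUNK = 200_000

    def _evaluate(self, points_mm, want_field: bool, tail: bool = False):
        pts_all = np.asarray(points_mm, dtype=float).reshape(-1, 3)
        if len(pts_all) > self._CHUNK:
            Vs, Es, tails = [], [], []
            for start in range(0, len(pts_all), self._CHUNK):
                block = pts_all[start : start + self._CHUNK]
                out = self._evaluate_block(block, want_field, tail)
                Vs.append(out[0])
                Es.append(out[1])
                if tail:
                    tails.append(out[0][0])
            if tail:
                return np.array([max(tails)]), None
            V = np.concatenate(Vs)
            E = np.concatenate(Es) if want_field else None
            return V, E
        return self._evaluate_block(pts_all, want_field, tail)

    def _evaluate_block(self, points_mm, want_field: bool, tail: bool = False):
        pts = np.asarray(points_mm, dtype=float).reshape(-1, 3) / 1000.0  # m
        radii = np.asarray(self.radii_mm, dtype=float) / 1000.0
        sig = np.asarray(self.sigmas_S_per_m, dtype=float)
        R = radii[-1]
        r = np.linalg.norm(pts, axis=1)
        if np.any(r > R * (1 + 1e-9)):
            raise EvaluationError("points outside the outer shell")
        r = np.clip(r, 1e-12, R)
        rhat = pts / r[:, None]
        shell = np.searchsorted(radii, r * (1 - 1e-12))
        shell = np.minimum(shell, len(radii) - 1)
        A, B, alpha_h = self._coefficients()
        I = self.current_mA * 1e-3

        V = np.zeros(len(pts))
        E = np.zeros((len(pts), 3)) if want_field else None
        tail_mag = 0.0
        for e_dir, sign in ((np.asarray(self.source, float), 1.0),
                            (np.asarray(self.sink, float), -1.0)):
            c = np.clip(rhat @ e_dir, -1.0, 1.0)
            at_electrode = (r > R * (1 - 1e-12)) & (c > 1 - 1e-12)
            if np.any(at_electrode):
                raise EvaluationError(
                    "evaluation point coincides with an electrode singularity"
                )
            Vp, Ep, tm = self._single_expansion(
                r, c, rhat, shell, e_dir, A, B, alpha_h, sig[-1], R, I, want_field
            )
            V += sign * Vp
            if want_field:
                E += sign * Ep
            tail_mag = max(tail_mag, tm)
        if tail:
            return np.array([tail_mag]), None
        return V, E

    def _single_expansion(
        self, r, c, rhat, shell, e_dir, A, B, alpha_h, sig_out, R, I, want_field
    ):
        N_sh = A.shape[0]
        outer = shell == N_sh - 1
        n_terms = self.n_terms

        # per-point running powers of the shell-normalized bases
        rj = (np.asarray(self.radii_mm, float) / 1000.0)[shell]
        t = r / rj  # (r/r_j); <= 1
        s = rj / r  # for the decaying basis (r/r_j)^-(n+1)
        s = np.where(shell == 0, 0.0, s)  # innermost shell has B = 0
        pa = t.copy()  # t^n starting at n=1
        pb = np.where(shell == 0, 0.0, s * s)  # s^(n+1) at n=1

        # effective A-coefficients: the homogeneous reference is subtracted in
        # the outer shell (its closed form is added back below); coefficient
        # columns are gathered per term to keep memory O(points), not
        # O(points x terms)

        Pm1 = np.ones_like(c)  # P_0
        P = c.copy()  # P_1
        dPm1 = np.zeros_like(c)  # P_0'
        dP = np.ones_like(c)  # P_1'
        V = np.zeros_like(c)
        Er_acc = np.zeros_like(c)  # sum f_n'(r) P_n
        G_acc = np.zeros_like(c)  # sum (f_n/r) P_n'
        last_term = np.zeros_like(c)
        for idx in range(n_terms):
            n = idx + 1
            Acol = A[:, idx][shell]
            if outer.any():
                Acol = Acol - np.where(outer, alpha_h[idx], 0.0)
            fa = Acol * pa
            fb = B[:, idx][shell] * pb
            f = fa + fb
            term = f * P
            V += term
            if want_field:
                fprime = (n * fa - (n + 1) * fb) / r
                Er_acc += fprime * P
                G_acc += (f / r) * dP
            if idx == n_terms - 1:
                last_term = term
            pa *= t
            pb *= s
            if n < n_terms:
                Pn1 = ((2 * n + 1) * c * P - n * Pm1) / (n + 1)
                dPn1 = dPm1 + (2 * n + 1) * P  # P'_{n+1} = P'_{n-1} + (2n+1) P_n
                dPm1, dP = dP, dPn1
                Pm1, P = P, Pn1

        E = None
        if want_field:
            # G_acc = sum (f_n/r) P_n'(c) already carries the 1/r factor
            E = -Er_acc[:, None] * rhat + G_acc[:, None] * (
                c[:, None] * rhat - e_dir[None, :]
            )

        # closed-form homogeneous part for outer-shell points
        if outer.any():
            K = I / (4 * np.pi * sig_out * R)
            tt = (r[outer] / R)
            cc = c[outer]
            u = np.sqrt(np.maximum(1 - 2 * tt * cc + tt * tt, 1e-30))
            g = 1 - tt * cc + u
            W = 2 / u - 2 + np.log(2.0 / g)
            V[outer] += K * W
            if want_field:
                u_t = (tt - cc) / u
                u_c = -tt / u
                W_t = -2 * u_t / u**2 - (-cc + u_t) / g
                W_c = -2 * u_c / u**2 - (-tt + u_c) / g
                V_r = K * W_t / R
                V_c = K * W_c
                E[outer] += (
                    -V_r[:, None] * rhat[outer]
                    + (V_c / r[outer])[:, None]
                    * (cc[:, None] * rhat[outer] - e_dir[None, :])
                )
        return V, E, float(np.max(np.abs(last_term)))


def sphere_voltage(m: SphereModel, points_mm: np.ndarray, demean: bool = True) -> np.ndarray:
    """Series voltage (V) of the source/sink pair at world points (mm)."""
    return m.voltage(points_mm, demean=demean)


def sphere_field(m: SphereModel, points_mm: np.ndarray) -> np.ndarray:
    """Analytic E-field vectors (V/m) at world points (mm)."""
    return m.field(points_mm)
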