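"""Pseudospectra, the transient index, and the stability classification.

For a square matrix M the epsilon-pseudospectrum is the set of complex z
where the smallest singular value of (zI - M) is at most epsilon —
equivalently, the union of eigenvalues of every perturbation M + E with
||E||_2 <= epsilon.  The pseudospectral radius rho_eps(M) is the largest
modulus of any such point, and the transient index

    T_eps = (rho_eps(M) - 1) / eps

measures how far structural noise of size eps can push the dynamics past
the unit circle.  Its supremum over eps (the Kreiss constant) lower-bounds
the peak of ||M^t||: sup_eps T_eps > 1 with all eigenvalues inside the unit
circle means perturbations are transiently amplified before decaying.

All norms here are spectral (2-)norms, the norm under which the
singular-value characterisation and the normal-matrix closed form
rho_eps = rho(M) + eps hold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import schur, svdvals

CLASSIFICATIONS = (
    "transiently_and_asymptotically_stable",
    "transiently_unstable_asymptotically_stable",
    "asymptotically_unstable",
)

#: default log-spaced epsilon grid: 1e-6 ... 1e2, 49 points (8 decades)
DEFAULT_EPS = np.logspace(-6.0, 2.0, 49)


def _as_schur(M):
    """Complex Schur form (triangular) sharing sigma_min with zI - M."""
    M = np.asarray(M)
    if M.shape[0] != M.shape[1]:
        raise ValueError("matrix must be square")
    T, _ = schur(M.astype(complex), output="complex")
    return T


def sigma_min(M, z: complex, _T=None) -> float:
    """Smallest singular value of (zI - M); zero iff z is an eigenvalue.

    A precomputed Schur factor may be passed to avoid re-reduction; the
    orthogonal similarity leaves every singular value unchanged.
    """
    T = _as_schur(M) if _T is None else _T
    A = z * np.eye(T.shape[0]) - T
    return float(svdvals(A)[-1])


def _support_function(M, n_dirs: int = 64):
    """Support function h(phi) of the numerical range W(M).

    h(phi) is the largest eigenvalue of the Hermitian part of e^{-i phi} M;
    W(M) lies in every half-plane {Re(z e^{-i phi}) <= h(phi)} and the
    eps-pseudospectrum within its eps-neighbourhood, which prunes the polar
    search cheaply.
    """
    M = np.asarray(M, dtype=complex)
    phis = np.linspace(0.0, 2.0 * np.pi, n_dirs, endpoint=False)
    h = np.empty(n_dirs)
    for i, phi in enumerate(phis):
        A = np.exp(-1j * phi) * M
        h[i] = float(np.linalg.eigvalsh(0.5 * (A + A.conj().T))[-1])
    return phis, h


def pseudo_radius(M, eps: float, n_angles: int = 180,
                  rtol: float = 1e-6, _cache: dict | None = None) -> float:
    """Pseudospectral radius max{|z| : sigma_min(zI - M, z) <= eps}.

    Radial search over a polar grid of angles (eigenvalue directions are
    always included), with three exact accelerations: the pseudospectrum is
    confined to the eps-neighbourhood of the numerical range (support-
    function bound, pruning whole rays); descending radial steps use the
    Lipschitz property |sigma_min(z1) - sigma_min(z2)| <= |z1 - z2|, so no
    boundary crossing can be jumped over; and the topmost crossing found is
    refined by bisection to relative tolerance ``rtol``.  The result is
    always >= rho(M) since the spectrum belongs to every pseudospectrum.

    ``_cache`` (a dict reused across calls on the same matrix) stores the
    Schur factor and support function.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    M = np.asarray(M)
    if _cache is None:
        _cache = {}
    if "T" not in _cache:
        _cache["T"] = _as_schur(M)
        _cache["eigs"] = np.diag(_cache["T"])
        _cache["support"] = _support_function(M)
    T = _cache["T"]
    eigs = _cache["eigs"]
    phis, hsup = _cache["support"]
    rho = float(np.max(np.abs(eigs)))

    def smin(z):
        return sigma_min(None, z, _T=T)

    def ray_upper(theta):
        # max radius at which sigma_min could still be <= eps along theta
        c = np.cos(theta - phis)
        ok = c > 1e-9
        if not np.any(ok):
            return np.inf
        return float(np.min((hsup[ok] + eps) / c[ok]))

    real_sym = np.isrealobj(M)
    ang = np.angle(eigs[np.abs(eigs) > 1e-12])
    if real_sym:
        # pseudospectrum is symmetric about the real axis
        grid = np.linspace(0.0, np.pi, max(n_angles // 2, 2) + 1)
        ang = np.abs(ang)
    else:
        grid = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
    angles = np.unique(np.concatenate([ang, grid]))
    eig_angles = set(np.round(ang, 12))
    ordered = sorted(angles, key=lambda a: (0 if round(a, 12) in eig_angles
                                            else 1))
    # a known lower bound (e.g. rho_eps' for eps' < eps) shrinks the search
    best = max(rho, float(_cache.get("lower_bound", 0.0)))
    min_step = rtol * max(rho + eps, 1.0)
    for theta in ordered:
        d = np.exp(1j * theta)
        if smin(best * d) <= eps:
            # incumbent radius is inside along this ray: push outward
            hi = ray_upper(theta)
            if np.isfinite(hi) and hi > best:
                lo, _ = _bisect(smin, d, best, hi, eps, rtol)
                best = max(best, lo)
            continue
        r = ray_upper(theta)
        prev = None
        while r > best + min_step:
            s = smin(r * d)
            if s <= eps:
                lo, _ = _bisect(smin, d, r, prev if prev is not None
                                else ray_upper(theta), eps, rtol)
                best = max(best, lo)
                break
            prev = r
            r -= max(s - eps, min_step)  # Lipschitz-safe descent
    return best


def _bisect(smin, d, lo, hi, eps, rtol):
    """Shrink [lo, hi] with smin(lo d) <= eps < smin(hi d)."""
    while hi - lo > rtol * max(hi, 1.0):
        mid = 0.5 * (lo + hi)
        if smin(mid * d) <= eps:
            lo = mid
        else:
            hi = mid
    return lo, hi


def transient_index(M, eps: float, **kw) -> float:
    """T_eps = (rho_eps(M) - 1) / eps."""
    return (pseudo_radius(M, eps, **kw) - 1.0) / eps


def sup_transient_index(M, eps_list=None, n_angles: int = 180):
    """Supremum of T_eps over a log-spaced epsilon grid.

    Returns ``(sup_T, argmax_eps, T_eps_array)``; warns when the argmax sits
    on an endpoint of the grid (the grid may be too narrow).  The epsilons
    are processed in ascending order so each pseudospectral radius seeds the
    next search (rho_eps is nondecreasing in eps).
    """
    eps_list = DEFAULT_EPS if eps_list is None else np.asarray(eps_list,
                                                               float)
    if eps_list.size == 0:
        raise ValueError("eps_list must be non-empty")
    if np.any(eps_list <= 0):
        raise ValueError("eps values must be > 0")
    cache: dict = {}
    order = np.argsort(eps_list)
    T = np.empty(len(eps_list))
    for i in order:
        r = pseudo_radius(M, eps_list[i], n_angles=n_angles, _cache=cache)
        cache["lower_bound"] = r
        T[i] = (r - 1.0) / eps_list[i]
    i = int(np.argmax(T))
    if i in (0, len(eps_list) - 1) and len(eps_list) > 1:
        warnings.warn("sup T_eps attained at an endpoint of the eps grid; "
                      "consider widening it", RuntimeWarning, stacklevel=2)
    return float(T[i]), float(eps_list[i]), T


@dataclass
class PseudospectrumResult:
    """Pseudospectral radii, transient indices and stability class."""

    eps_list: np.ndarray
    rho_eps: np.ndarray
    T_eps: np.ndarray
    sup_T: float
    argmax_eps: float
    spectral_radius: float
    classification: str = ""
    borderline: bool = False
    sigma_min_field: np.ndarray | None = None

    def to_json(self, path=None) -> str:
        payload = dict(eps_list=self.eps_list.tolist(),
                       rho_eps=self.rho_eps.tolist(),
                       T_eps=self.T_eps.tolist(),
                       sup_T=self.sup_T, argmax_eps=self.argmax_eps,
                       spectral_radius=self.spectral_radius,
                       classification=self.classification,
                       borderline=self.borderline)
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def classify_stability(result: PseudospectrumResult,
                       tol: float = 1e-8) -> str:
    """Three-way classification from rho(M) and sup T_eps.

    Eigenvalues outside the unit circle: asymptotically (and transiently)
    unstable.  Otherwise sup T_eps > 1 marks transient instability with
    asymptotic stability; sup T_eps < 1 marks full stability.  A sup within
    tol of 1 sets the borderline flag.
    """
    if result.spectral_radius > 1.0 + tol:
        result.classification = "asymptotically_unstable"
    elif result.sup_T > 1.0 + tol:
        result.classification = "transiently_unstable_asymptotically_stable"
    else:
        result.classification = "transiently_and_asymptotically_stable"
    result.borderline = abs(result.sup_T - 1.0) <= tol
    return result.classification


def analyze(M, eps_list=None, n_angles: int = 180, tol: float = 1e-8,
            field_grid: int = 0) -> PseudospectrumResult:
    """Full pseudospectral work-up of one matrix."""
    eps_list = DEFAULT_EPS if eps_list is None else np.asarray(eps_list,
                                                               float)
    rho = float(np.max(np.abs(np.linalg.eigvals(np.asarray(M)))))
    sup_T, arg_eps, T = sup_transient_index(M, eps_list, n_angles=n_angles)
    rho_eps = T * eps_list + 1.0
    res = PseudospectrumResult(eps_list=eps_list, rho_eps=rho_eps, T_eps=T,
                               sup_T=sup_T, argmax_eps=arg_eps,
                               spectral_radius=rho)
    classify_stability(res, tol=tol)
    if field_grid:
        res.sigma_min_field = sigma_min_field(M, n=field_grid)
    return res


def sigma_min_field(M, n: int = 201, box_scale: float = 1.5):
    """sigma_min(zI - M) on an n x n complex-plane grid (for contour plots).

    The box spans ``box_scale`` times the spectral radius in each direction.
    """
    M = np.asarray(M)
    T = _as_schur(M)
    rho = max(float(np.max(np.abs(np.diag(T)))), 1e-3)
    r = box_scale * rho
    re = np.linspace(-r, r, n)
    im = np.linspace(-r, r, n)
    out = np.empty((n, n))
    for i, b in enumerate(im):
        for j, a in enumerate(re):
            out[i, j] = sigma_min(None, a + 1j * b, _T=T)
    return out


def transient_envelope(M, T_max: int):
    """Spectral norms of the matrix powers M^t for t = 0 .. T_max.

    Returns ``(norms, peak, peak_time)``; norms[0] = 1 by convention.
    The peak always dominates the Kreiss bound sup T_eps.
    """
    if T_max < 1:
        raise ValueError("T_max must be >= 1")
    M = np.asarray(M, dtype=float)
    norms = np.empty(T_max + 1)
    norms[0] = 1.0
    P = np.eye(M.shape[0])
    for t in range(1, T_max + 1):
        P = P @ M
        norms[t] = svdvals(P)[0]
    peak_time = int(np.argmax(norms))
    return norms, float(norms[peak_time]), peak_time
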