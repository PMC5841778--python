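"""Estimation engine for the SITAR shape-invariant growth model.

The model for an observation of subject *i* (cohort *c*) at transformed
age *t* is::

    y = s(u) + a_c + a_i + e,      u = exp(g_c + g_i) * (t - b_c - b_i)

where ``s`` is a natural cubic regression spline plus an intercept,
``(a_i, b_i, g_i)`` are the subject's size / tempo / velocity random
effects (mean zero, unstructured 3x3 covariance), ``(a_c, b_c, g_c)``
are fixed offsets for non-reference cohorts, and the residual variance
is cohort-specific.  Under the default log-age transform, tempo is a
proportional age shift (convertible to years via the geometric mean
age) and velocity a proportional stretch of the age axis (x100 ~ %).

Sign convention: positive velocity ``g`` *compresses* the age axis,
i.e. the subject traverses the curve faster; positive tempo ``b``
shifts the pattern later.

Fitting is maximum likelihood by an alternating scheme in the spirit of
Lindstrom-Bates:

1. PNLS: penalized least squares over the subject random effects
   (vectorized per-subject Gauss-Newton with persistent Levenberg
   damping) and the linear/global fixed effects (damped GLS, which is
   the exact joint Gauss-Newton direction with the random effects
   profiled out), plus likelihood-invariant recentring of mean random
   effects into the fixed parameters;
2. LME: a full ML solve of the linearized mixed model for the variance
   components (EM warm-up, then direct L-BFGS with analytic gradients
   on a Cholesky/log parametrization);
3. a final damped-Newton polish of the cohort offsets against the
   Laplace marginal likelihood itself, whose determinant term the
   penalized least-squares view omits.

Iterated until the Laplace-approximate marginal log-likelihood is
stationary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import spline as spl
from .records import MeasurementRecord, SitarConfig

logger = logging.getLogger(__name__)

RE_NAMES = ("size", "tempo", "velocity")

# variance-component initialization: the size variance starts at a fraction
# of the raw outcome variance, tempo/velocity at a small positive value so
# that early iterations keep subjects near the pooled mean curve while the
# EM steps grow the variances to their supported level
_INIT_SIZE_VAR_FRAC = 0.1
_INIT_TV_VAR = 0.01
_DEBUG = False

__all__ = [
    "RandomEffects",
    "CohortContrast",
    "SitarFit",
    "fit_sitar",
    "marginal_loglik",
    "predict_curve",
    "velocity_curve",
    "age_at_peak_velocity",
    "cohort_contrasts",
    "summarize_random_effects",
    "export_curves",
]


# ---------------------------------------------------------------------------
# result types
# ---------------------------------------------------------------------------

@dataclass
class RandomEffects:
    """A subject's size/tempo/velocity triple.

    ``size`` is in trait units (cm or kg); ``tempo`` and ``velocity``
    are on the transformed-age scale (dimensionless under the log-age
    transform).
    """

    subject_id: str
    size: float
    tempo: float
    velocity: float

    def as_array(self) -> np.ndarray:
        return np.array([self.size, self.tempo, self.velocity])

    def tempo_in_years(self, geometric_mean_age: float) -> float:
        return self.tempo * geometric_mean_age


@dataclass
class CohortContrast:
    """A cohort's fixed offsets relative to the reference, in reporting units."""

    cohort_id: str
    trait: str
    size_delta: float
    size_ci: tuple[float, float]
    tempo_delta_years: float
    tempo_ci: tuple[float, float]
    velocity_delta_pct: float
    velocity_ci: tuple[float, float]


@dataclass
class APVResult:
    """Age at peak velocity; ``interior`` is False when no interior maximum exists."""

    age: float
    interior: bool


@dataclass
class SitarFit:
    """A fitted shape-invariant growth model."""

    trait: str
    sex: str
    config: SitarConfig
    spline_spec: spl.SplineSpec
    intercept: float
    spline_coefs: np.ndarray              # (df,)
    cohort_ids: list[str]                 # reference first
    cohort_offsets: dict[str, np.ndarray]  # cohort -> (size, tempo, velocity); ref = zeros
    offset_se: dict[str, np.ndarray]      # same layout; NaN where effect disabled
    re_cov: np.ndarray                    # (3, 3), zero rows/cols for inactive effects
    residual_sd: dict[str, float]
    blups: list[RandomEffects]
    subject_cohorts: dict[str, str]       # subject_id -> cohort_id
    loglik: float
    converged: bool
    n_iter: int
    geometric_mean_age: float
    age_center: float          # subtracted from the transformed age before the spline
    n_subjects: int
    n_records: int
    ll_trace: list = field(default_factory=list)  # approx marginal ll per outer iteration
    # global (all-cohort) tempo and velocity fixed effects: the overall
    # timing shift / age-scale stretch that a fixed-knot spline cannot absorb
    global_shift: tuple[float, float] = (0.0, 0.0)

    @property
    def reference_cohort(self) -> str:
        return self.cohort_ids[0]

    def blup_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "subject_id": [b.subject_id for b in self.blups],
                "size": [b.size for b in self.blups],
                "tempo": [b.tempo for b in self.blups],
                "velocity": [b.velocity for b in self.blups],
            }
        )


# ---------------------------------------------------------------------------
# internal data preparation
# ---------------------------------------------------------------------------

class _Data:
    """Vectorized view of the measurement records for one fit."""

    def __init__(self, records: list[MeasurementRecord], config: SitarConfig,
                 center: float | None = None):
        records = [r for r in records if not r.excluded]
        if not records:
            raise ValueError("no (non-excluded) records to fit")
        traits = {r.trait for r in records}
        if len(traits) > 1:
            raise ValueError(f"records mix traits {sorted(traits)}; fit one trait at a time")
        sexes = {r.sex for r in records}
        if len(sexes) > 1:
            raise ValueError(f"records mix sexes {sorted(sexes)}; fit one sex at a time")
        self.trait = records[0].trait
        self.sex = records[0].sex

        subj_order: dict[str, int] = {}
        for r in records:
            if r.subject_id not in subj_order:
                subj_order[r.subject_id] = len(subj_order)
        self.subjects = list(subj_order)

        cohorts = sorted({r.cohort_id for r in records})
        ref = config.reference_cohort
        if ref is None:
            ref = cohorts[0]
        if ref not in cohorts:
            raise ValueError(f"reference cohort {ref!r} not present in the data")
        self.cohort_ids = [ref] + [c for c in cohorts if c != ref]
        coh_index = {c: k for k, c in enumerate(self.cohort_ids)}

        self.age = np.array([r.age for r in records])
        self.y = np.array([r.value for r in records])
        self.subj = np.array([subj_order[r.subject_id] for r in records])
        self.coh = np.array([coh_index[r.cohort_id] for r in records])
        # transformed age, centered so that the velocity stretch pivots at
        # the (geometric) mean age rather than at age 1
        if config.age_transform == "log":
            raw = np.log(self.age)
        else:
            raw = self.age.copy()
        if center is None:
            center = config.age_center
        self.center = float(raw.mean()) if center is None else float(center)
        self.t = raw - self.center
        self.n_subj = len(self.subjects)
        self.n_coh = len(self.cohort_ids)
        self.n = self.y.size
        self.geometric_mean_age = float(np.exp(np.mean(np.log(self.age))))
        self.obs_per_subject = np.bincount(self.subj, minlength=self.n_subj)
        # cohort of each subject (cohort never changes within subject)
        self.subj_coh = np.zeros(self.n_subj, dtype=int)
        self.subj_coh[self.subj] = self.coh


def _segsum(idx: np.ndarray, n: int, arr: np.ndarray) -> np.ndarray:
    """Sum ``arr`` (N,) or (N, k) within groups given by ``idx``."""
    if arr.ndim == 1:
        return np.bincount(idx, weights=arr, minlength=n)
    out = np.empty((n, arr.shape[1]))
    for j in range(arr.shape[1]):
        out[:, j] = np.bincount(idx, weights=arr[:, j], minlength=n)
    return out


def _segsum_outer(idx: np.ndarray, n: int, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Per-group sums of a_r b_r^T for row vectors a_r (ka,) and b_r (kb,)."""
    ka, kb = A.shape[1], B.shape[1]
    out = np.empty((n, ka, kb))
    for i in range(ka):
        for j in range(kb):
            out[:, i, j] = np.bincount(idx, weights=A[:, i] * B[:, j], minlength=n)
    return out


# ---------------------------------------------------------------------------
# model terms
# ---------------------------------------------------------------------------

def _effective_offsets(O: np.ndarray) -> np.ndarray:
    """Per-cohort total offsets.

    Row 0 holds the *global* tempo/velocity fixed effects (the reference
    cohort's size lives in the intercept); rows >= 1 hold each non-reference
    cohort's contrast, so their totals add the global row.
    """
    Oe = O.copy()
    if Oe.shape[0] > 1:
        Oe[1:, 1] += O[0, 1]
        Oe[1:, 2] += O[0, 2]
    return Oe


def _terms(spec, intercept, coefs, O, U, data: _Data):
    """Mean values and pieces of the Jacobian at the current parameters.

    Returns (f, u, eg, sprime) where ``sprime`` is s'(u).
    """
    Oe = _effective_offsets(O)
    a = Oe[data.coh, 0] + U[data.subj, 0]
    b = Oe[data.coh, 1] + U[data.subj, 1]
    g = Oe[data.coh, 2] + U[data.subj, 2]
    eg = np.exp(np.clip(g, -40.0, 40.0))
    u = eg * (data.t - b)
    B = spl.basis(spec, u)
    f = intercept + B @ coefs + a
    sprime = spl.basis_derivative(spec, u) @ coefs
    return f, u, eg, sprime, B


def _z_matrix(u, eg, sprime, active):
    """Per-record Jacobian rows for the (size, tempo, velocity) triple."""
    cols = []
    for j in active:
        if j == 0:
            cols.append(np.ones_like(u))
        elif j == 1:
            cols.append(-eg * sprime)
        else:
            cols.append(u * sprime)
    return np.column_stack(cols)


def _psi_inv(psi_a: np.ndarray) -> tuple[np.ndarray, float]:
    """Inverse of the active random-effect covariance with an eigenvalue floor."""
    lam, V = np.linalg.eigh(psi_a)
    floor = max(1e-12, 1e-10 * max(lam.max(), 0.0))
    lam = np.clip(lam, floor, None)
    inv = (V / lam) @ V.T
    return inv, float(np.sum(np.log(lam)))


# ---------------------------------------------------------------------------
# inner step: subject random effects by penalized Gauss-Newton
# ---------------------------------------------------------------------------

def _inner_gn(data, spec, intercept, coefs, O, psi_a, sig2, U, active,
              max_iter=25, tol=1e-9):
    """Maximize the joint (penalized) objective over every subject's triple.

    Vectorized per-subject Gauss-Newton with backtracking.  Backtracking
    rounds re-evaluate only the records of subjects whose step was
    rejected, so a handful of hard subjects does not force repeated
    passes over the full data.
    """
    k = len(active)
    S = data.n_subj
    psi_inv, _ = _psi_inv(psi_a)
    w8 = 1.0 / sig2[data.coh]
    Ua = U[:, active].copy()
    Oe = _effective_offsets(O)
    t = data.t
    coh = data.subj_coh  # per-subject cohort (records share the subject's cohort)

    def expand(Ua_):
        U_ = np.zeros((S, 3))
        U_[:, active] = Ua_
        return U_

    def q_subset(Ua_, rec_mask=None):
        """Per-subject penalized objective, optionally on a record subset."""
        U3 = expand(Ua_)
        if rec_mask is None:
            subj, tt, y, ww, ch = data.subj, t, data.y, w8, data.coh
        else:
            subj = data.subj[rec_mask]
            tt, y, ww, ch = t[rec_mask], data.y[rec_mask], w8[rec_mask], data.coh[rec_mask]
        a = Oe[ch, 0] + U3[subj, 0]
        b = Oe[ch, 1] + U3[subj, 1]
        g = Oe[ch, 2] + U3[subj, 2]
        u = np.exp(np.clip(g, -40.0, 40.0)) * (tt - b)
        f = intercept + spl.basis(spec, u) @ coefs + a
        res = y - f
        q = _segsum(subj, S, res * res * ww)
        q += np.einsum("si,ij,sj->s", Ua_, psi_inv, Ua_)
        return q

    q_cur = q_subset(Ua)
    scale = np.sqrt(np.maximum(np.diag(psi_a)[list(active)], 1e-12))
    diag_idx = np.arange(k)
    lam = np.full(S, 1e-8)  # per-subject Levenberg damping, persistent
    for _ in range(max_iter):
        f, u, eg, sprime, _ = _terms(spec, intercept, coefs, O, expand(Ua), data)
        res = data.y - f
        Z = _z_matrix(u, eg, sprime, active)
        Zw = Z * w8[:, None]
        A = _segsum_outer(data.subj, S, Z, Zw) + psi_inv[None]
        rhs = _segsum(data.subj, S, Zw * res[:, None]) - Ua @ psi_inv
        dA = A[:, diag_idx, diag_idx]

        def _dstep(which):
            Ad = A[which].copy()
            Ad[:, diag_idx, diag_idx] += lam[which, None] * dA[which]
            return np.linalg.solve(Ad, rhs[which, :, None])[..., 0]

        all_s = np.ones(S, dtype=bool)
        cand = Ua + _dstep(all_s)
        q_cand = q_subset(cand)
        bad = q_cand > q_cur + 1e-10 * (1.0 + np.abs(q_cur))
        lam[~bad] = np.maximum(lam[~bad] / 3.0, 1e-10)
        for _bt in range(10):
            if not bad.any():
                break
            lam[bad] = np.minimum(lam[bad] * 10.0, 1e10)
            cand[bad] = Ua[bad] + _dstep(bad)
            rec_mask = bad[data.subj]
            q_new = q_subset(cand, rec_mask)
            q_cand = np.where(bad, q_new, q_cand)
            bad = bad & (q_cand > q_cur + 1e-10 * (1.0 + np.abs(q_cur)))
        if bad.any():
            cand[bad] = Ua[bad]
            q_cand[bad] = q_cur[bad]
        moved = np.abs(cand - Ua) / (scale[None, :] + 1e-12)
        Ua = cand
        q_cur = np.minimum(q_cand, q_cur)
        if moved.max() < tol:
            break
    return expand(Ua)


# ---------------------------------------------------------------------------
# linearized-model quantities (GLS, EM, log-likelihood)
# ---------------------------------------------------------------------------

def _pack_layout(data: _Data, config: SitarConfig, df: int, active=(0, 1, 2),
                 contrasts: bool = True):
    """Column layout of the fixed-effects design.

    Intercept and spline first, then the global tempo/velocity fixed
    effects (cohort index 0 — they keep the random effects mean zero,
    since a fixed-knot spline cannot absorb an affine re-map of its
    domain), then (optionally) the per-cohort offset contrasts.
    """
    layout = []  # (cohort_index, effect_index); cohort 0 = global
    for j in (1, 2):
        if j in active:
            layout.append((0, j))
    if contrasts:
        for c in range(1, data.n_coh):
            for j, on in enumerate(config.cohort_effects):
                if on:
                    layout.append((c, j))
    p = 1 + df + len(layout)
    return layout, p


def _design(data, spec, intercept, coefs, O, U, config, active,
            include_offsets: bool = True):
    """Linearization at the current parameters.

    Returns (X, Z, w, beta, layout) where w is the Lindstrom-Bates
    pseudo-response and beta the current packed fixed-effect vector
    (intercept, spline coefficients, then cohort offsets when
    ``include_offsets``).
    """
    f, u, eg, sprime, B = _terms(spec, intercept, coefs, O, U, data)
    Z = _z_matrix(u, eg, sprime, active)
    layout, p = _pack_layout(data, config, spec.df, active,
                             contrasts=include_offsets)
    N = data.n
    X = np.empty((N, p))
    X[:, 0] = 1.0
    X[:, 1 : 1 + spec.df] = B
    beta = np.empty(p)
    beta[0] = intercept
    beta[1 : 1 + spec.df] = coefs
    zfull = {0: np.ones(N), 1: -eg * sprime, 2: u * sprime}
    for col, (c, j) in enumerate(layout, start=1 + spec.df):
        if c == 0:
            X[:, col] = zfull[j]          # global tempo/velocity fixed effect
        else:
            X[:, col] = np.where(data.coh == c, zfull[j], 0.0)
        beta[col] = O[c, j]
    res = data.y - f
    w = res + X @ beta + np.einsum("rk,rk->r", Z, U[data.subj][:, active])
    return X, Z, w, beta, layout


def _cond_cov(psi: np.ndarray, ZtZw: np.ndarray) -> np.ndarray:
    """Per-subject conditional covariance (Psi^-1 + Z'WZ)^-1, stably.

    Uses the Woodbury form (safe for singular Psi); falls back to the
    precision form with an eigenvalue-floored Psi inverse when extreme
    weights (near-zero residual variance) make the Woodbury system
    ill-conditioned.
    """
    S, k, _ = ZtZw.shape
    Ik = np.eye(k)
    try:
        Dm = Ik[None] + np.einsum("ij,sjl->sil", psi, ZtZw)
        C = np.linalg.solve(Dm, np.broadcast_to(psi, (S, k, k)))
    except np.linalg.LinAlgError:
        psi_inv, _ = _psi_inv(psi)
        C = np.linalg.inv(psi_inv[None] + ZtZw)
    return 0.5 * (C + np.transpose(C, (0, 2, 1)))


def _lin_stats(data, X, Z, w, beta, psi_a, sig2):
    """Sufficient statistics of the linearized mixed model.

    Uses the singularity-safe Woodbury form: with G the random-effect
    covariance, C_s = (I + G Z'WZ)^(-1) G is the conditional covariance
    and u_s = C_s Z'W r the conditional mean (BLUP).
    """
    S = data.n_subj
    k = Z.shape[1]
    w8 = 1.0 / sig2[data.coh]
    r = w - X @ beta
    Zw = Z * w8[:, None]
    ZtZw = _segsum_outer(data.subj, S, Z, Zw)                # (S, k, k)
    Ztrw = _segsum(data.subj, S, Zw * r[:, None])            # (S, k)
    G = psi_a
    Dm = np.eye(k)[None] + np.einsum("ij,sjl->sil", G, ZtZw)  # I + G Z'WZ
    C = _cond_cov(G, ZtZw)
    u_hat = np.einsum("skl,sl->sk", C, Ztrw)
    sign, logdet_Dm = np.linalg.slogdet(Dm)
    rVr = float(np.sum(r * r * w8) - np.einsum("sk,sk->", Ztrw, u_hat))
    logdet_V = float(np.sum(np.log(sig2[data.coh])) + logdet_Dm.sum())
    ll = -0.5 * (data.n * np.log(2 * np.pi) + logdet_V + rVr)
    return {
        "r": r, "ZtZw": ZtZw, "Ztrw": Ztrw, "C": C, "u_hat": u_hat,
        "ll": ll, "w8": w8,
    }


def _gls_system(data, X, Z, w, psi_a, sig2):
    """Normal-equation pieces (A, b) of the GLS problem for the fixed effects.

    ``A`` is X'V^-1X and ``b`` is X'V^-1w, assembled subject-by-subject
    through the Woodbury identity.
    """
    S = data.n_subj
    k = Z.shape[1]
    w8 = 1.0 / sig2[data.coh]
    Xw = X * w8[:, None]
    XtX = Xw.T @ X
    Xtw = Xw.T @ w
    XtZw = _segsum_outer(data.subj, S, Xw, Z)                 # X'WZ per subject
    ZtZw = _segsum_outer(data.subj, S, Z, Z * w8[:, None])
    Ztww = _segsum(data.subj, S, Z * (w * w8)[:, None])
    C = _cond_cov(psi_a, ZtZw)                                # = (Psi^-1 + Z'WZ)^-1
    A = XtX - np.einsum("spk,skl,sql->pq", XtZw, C, XtZw)
    b = Xtw - np.einsum("spk,skl,sl->p", XtZw, C, Ztww)
    return 0.5 * (A + A.T), b


def _gls_beta(data, X, Z, w, psi_a, sig2):
    """One-shot GLS estimate of the fixed effects plus its covariance."""
    A, b = _gls_system(data, X, Z, w, psi_a, sig2)
    try:
        beta = np.linalg.solve(A, b)
        cov = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise ValueError("rank-deficient fixed-effect design in GLS step") from exc
    return beta, cov


def _lme_direct(data, blocks, psi0, sig20, per_cohort_residual,
                maxiter=120):
    """Direct ML of the linearized mixed model's variance components.

    Maximizes the profiled (over the fixed effects) log-likelihood over
    a Cholesky parametrization of the random-effect covariance and log
    residual variances, with analytic gradients, via L-BFGS-B.  Much
    faster than EM when the covariance is nearly singular (e.g. strongly
    correlated size/velocity effects).
    """
    from scipy.optimize import minimize

    (ZtZ, XtZ, Ztw, XtX_s, Xtw_s, ww_s, subj_coh, n_rec_coh) = blocks
    S, k = Ztw.shape
    n_coh = n_rec_coh.size
    Ik = np.eye(k)
    tril = np.tril_indices(k)

    # initial Cholesky (with a tiny floor so L-BFGS can move)
    lam0, V0 = np.linalg.eigh(psi0)
    psi_start = (V0 * np.clip(lam0, 1e-10, None)) @ V0.T
    L0 = np.linalg.cholesky(psi_start + 1e-12 * Ik)
    n_sig = n_coh if per_cohort_residual else 1
    theta0 = np.concatenate([L0[tril], np.log(sig20[:n_sig])])

    def unpack(theta):
        L = np.zeros((k, k))
        L[tril] = theta[: tril[0].size]
        psi = L @ L.T
        if per_cohort_residual:
            sig2 = np.exp(np.clip(theta[tril[0].size:], -60.0, 60.0))
        else:
            sig2 = np.full(n_coh, np.exp(np.clip(theta[tril[0].size], -60.0, 60.0)))
        return L, psi, np.maximum(sig2, 1e-12)

    def negll_grad(theta):
        L, psi, sig2 = unpack(theta)
        w8s = 1.0 / sig2[subj_coh]
        ZtZw = ZtZ * w8s[:, None, None]
        Dm = Ik[None] + np.einsum("ij,sjl->sil", psi, ZtZw)
        C = np.linalg.solve(Dm, np.broadcast_to(psi, (S, k, k)))
        C = 0.5 * (C + np.transpose(C, (0, 2, 1)))
        # GLS beta
        A = np.einsum("s,spq->pq", w8s, XtX_s)
        A -= np.einsum("s,spk,skl,sql->pq", w8s**2, XtZ, C, XtZ)
        b = np.einsum("s,sp->p", w8s, Xtw_s)
        b -= np.einsum("s,spk,skl,sl->p", w8s**2, XtZ, C, Ztw)
        A = 0.5 * (A + A.T)
        beta = np.linalg.solve(A, b)
        Ztr = Ztw - np.einsum("spk,p->sk", XtZ, beta)          # Z'r unweighted
        Ztrw = Ztr * w8s[:, None]
        u_hat = np.einsum("skl,sl->sk", C, Ztrw)
        rr_s = ww_s - 2 * Xtw_s @ beta + np.einsum("spq,p,q->s", XtX_s, beta, beta)
        quad_s = rr_s * w8s - np.einsum("sk,sk->s", Ztrw, u_hat)  # r'V^-1 r
        sign, logdet_Dm = np.linalg.slogdet(Dm)
        if np.all(sig2 == sig2[0]):
            logdet_sig = data.n * np.log(sig2[0])
        else:
            logdet_sig = float(np.sum(n_rec_coh * np.log(sig2)))
        ll = -0.5 * (
            data.n * np.log(2 * np.pi)
            + logdet_sig
            + float(logdet_Dm.sum())
            + float(quad_s.sum())
        )
        # gradient wrt psi: -1/2 [sum Z'V^-1 Z - sum (Z'V^-1 r)(...)']
        ZtVZ = ZtZw - np.einsum("sij,sjl,slm->sim", ZtZw, C, ZtZw)
        ZtVr = Ztrw - np.einsum("sij,sj->si", ZtZw, u_hat)      # Z'V^-1 r
        G_psi = -0.5 * (ZtVZ.sum(axis=0) - np.einsum("si,sj->ij", ZtVr, ZtVr))
        G_L = 2.0 * G_psi @ L
        # gradient wrt log sig2 per cohort
        n_s = np.bincount(data.subj, minlength=S).astype(float)
        trV_s = w8s * n_s - w8s * np.einsum("sij,sji->s", C, ZtZw)
        res2_s = (
            rr_s
            - 2 * np.einsum("sk,sk->s", Ztr, u_hat)
            + np.einsum("sk,skl,sl->s", u_hat, ZtZ, u_hat)
        )
        ee_s = w8s**2 * res2_s                                   # ||V^-1 r||^2 part
        if per_cohort_residual:
            g_sig = -0.5 * (
                np.bincount(subj_coh, weights=trV_s, minlength=n_coh)
                - np.bincount(subj_coh, weights=ee_s, minlength=n_coh)
            ) * sig2
        else:
            g_sig = np.array([-0.5 * (trV_s.sum() - ee_s.sum()) * sig2[0]])
        grad = np.concatenate([G_L[tril], g_sig[:n_sig]])
        return -ll, -grad

    res = minimize(negll_grad, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8})
    L, psi, sig2 = unpack(res.x)
    # final GLS beta and covariance at the optimum
    w8s = 1.0 / sig2[subj_coh]
    ZtZw = ZtZ * w8s[:, None, None]
    Dm = Ik[None] + np.einsum("ij,sjl->sil", psi, ZtZw)
    C = np.linalg.solve(Dm, np.broadcast_to(psi, (S, k, k)))
    C = 0.5 * (C + np.transpose(C, (0, 2, 1)))
    A = np.einsum("s,spq->pq", w8s, XtX_s)
    A -= np.einsum("s,spk,skl,sql->pq", w8s**2, XtZ, C, XtZ)
    b = np.einsum("s,sp->p", w8s, Xtw_s)
    b -= np.einsum("s,spk,skl,sl->p", w8s**2, XtZ, C, Ztw)
    A = 0.5 * (A + A.T)
    beta = np.linalg.solve(A, b)
    cov = np.linalg.inv(A)
    return beta, cov, psi, sig2, -res.fun


def _recentre(data, config, active, intercept, O, U):
    """Move mean random effects into the fixed parameters (in place).

    Offsets, global shifts and random effects enter the model additively,
    so these transfers are exactly likelihood-invariant.  They keep the
    random effects mean zero: per-cohort means go to the cohort's own
    offset where one exists; the remaining pooled size mean goes to the
    intercept and the pooled tempo/velocity means to the global fixed
    shifts (a fixed-knot spline cannot absorb an affine re-map of its
    domain, so those two need explicit parameters).  Returns the updated
    intercept.
    """
    if 0 in active:
        no_off = np.array([
            c == 0 or not config.cohort_effects[0] for c in range(data.n_coh)
        ])
        members = no_off[data.subj_coh]
        if members.any():
            m = U[members, 0].mean()
            intercept += m
            U[members, 0] -= m
    for j in (1, 2):
        if j not in active:
            continue
        pooled = np.array([
            c == 0 or not config.cohort_effects[j] for c in range(data.n_coh)
        ])
        members = pooled[data.subj_coh]
        if members.any():
            m = U[members, j].mean()
            O[0, j] += m
            for c in range(1, data.n_coh):
                if not pooled[c]:
                    O[c, j] -= m
            U[members, j] -= m
    for c in range(1, data.n_coh):
        members = data.subj_coh == c
        if not members.any():
            continue
        for j in range(3):
            if j in active and config.cohort_effects[j]:
                m = U[members, j].mean()
                O[c, j] += m
                U[members, j] -= m
    return intercept


def _lme_solve(data, X, Z, w, psi0, sig20, per_cohort_residual,
               max_em=300, rtol=1e-9, em_warmup=30):
    """Full ML solve of the linear mixed model on fixed pseudo-data.

    Given the LB linearization (X, Z, w fixed), alternate GLS for the
    fixed effects with EM for the variance components until the linear
    model's log-likelihood is stationary.  All per-subject blocks are
    precomputed, so iterations are cheap.
    """
    S = data.n_subj
    k = Z.shape[1]
    p = X.shape[1]
    n_coh = data.n_coh
    # unweighted per-subject / per-cohort blocks
    ZtZ = _segsum_outer(data.subj, S, Z, Z)
    XtZ = _segsum_outer(data.subj, S, X, Z)
    Ztw = _segsum(data.subj, S, Z * w[:, None])
    XtX_s = _segsum_outer(data.subj, S, X, X)
    Xtw_s = _segsum(data.subj, S, X * w[:, None])
    ww_s = _segsum(data.subj, S, w * w)
    subj_coh = data.subj_coh
    n_rec_coh = np.bincount(data.coh, minlength=n_coh).astype(float)

    psi, sig2 = psi0.copy(), sig20.copy()
    ll_prev = None
    beta = None
    cov = None
    Ik = np.eye(k)
    for _ in range(min(max_em, em_warmup)):
        w8s = 1.0 / sig2[subj_coh]                      # per-subject weight
        ZtZw = ZtZ * w8s[:, None, None]
        Dm = Ik[None] + np.einsum("ij,sjl->sil", psi, ZtZw)
        C = _cond_cov(psi, ZtZw)                        # (Psi^-1 + Z'WZ)^-1
        # GLS for beta
        A = np.einsum("s,spq->pq", w8s, XtX_s)
        A -= np.einsum("s,spk,skl,sql->pq", w8s**2, XtZ, C, XtZ)
        b = np.einsum("s,sp->p", w8s, Xtw_s)
        b -= np.einsum("s,spk,skl,sl->p", w8s**2, XtZ, C, Ztw)
        A = 0.5 * (A + A.T)
        try:
            beta = np.linalg.solve(A, b)
            cov = np.linalg.inv(A)
        except np.linalg.LinAlgError as exc:
            raise ValueError("rank-deficient fixed-effect design in LME step") from exc
        # conditional moments and log-likelihood
        Ztr = (Ztw - np.einsum("spk,p->sk", XtZ, beta)) * w8s[:, None]
        u_hat = np.einsum("skl,sl->sk", C, Ztr)
        rr_s = ww_s - 2 * Xtw_s @ beta + np.einsum("spq,p,q->s", XtX_s, beta, beta)
        rVr = float(np.sum(rr_s * w8s) - np.einsum("sk,sk->", Ztr, u_hat))
        sign, logdet_Dm = np.linalg.slogdet(Dm)
        logdet_V = float(n_rec_coh.sum() * np.log(sig2[0]) + logdet_Dm.sum()) \
            if np.all(sig2 == sig2[0]) else \
            float(np.sum(n_rec_coh * np.log(sig2)) + logdet_Dm.sum())
        ll = -0.5 * (data.n * np.log(2 * np.pi) + logdet_V + rVr)
        if ll_prev is not None and abs(ll - ll_prev) <= rtol * max(1.0, abs(ll)):
            ll_prev = ll
            break
        ll_prev = ll
        # EM updates
        psi = (u_hat.T @ u_hat + C.sum(axis=0)) / S
        psi = 0.5 * (psi + psi.T)
        # residual variances: E||r - Zu||^2 per cohort
        ZtZu = np.einsum("skl,sl->sk", ZtZ, u_hat)
        res2_s = (
            rr_s
            - 2 * np.einsum("sk,sk->s", Ztr, u_hat) / w8s
            + np.einsum("sk,sk->s", u_hat, ZtZu)
            + np.einsum("skl,slk->s", ZtZ, C)
        )
        if per_cohort_residual:
            coh_sum = np.bincount(subj_coh, weights=res2_s, minlength=n_coh)
            sig2 = np.maximum(coh_sum / np.maximum(n_rec_coh, 1.0), 1e-12)
        else:
            sig2 = np.full(n_coh, max(res2_s.sum() / n_rec_coh.sum(), 1e-12))
    # quasi-Newton polish of the variance components: EM alone converges
    # extremely slowly when the random-effect covariance is nearly
    # singular (strong size-velocity correlation).  Degenerate problems
    # (residual variance at its floor) keep the EM solution.
    blocks = (ZtZ, XtZ, Ztw, XtX_s, Xtw_s, ww_s, subj_coh, n_rec_coh)
    try:
        b2, c2, p2, s2, ll2 = _lme_direct(
            data, blocks, psi, sig2, per_cohort_residual,
            maxiter=max(40, max_em // 2),
        )
        ok = (
            np.all(np.isfinite(p2)) and np.all(np.isfinite(s2))
            and np.all(np.isfinite(b2)) and np.isfinite(ll2)
            and np.linalg.eigvalsh(p2).min() > -1e-8
            and (ll_prev is None or ll2 >= ll_prev - 1e-6 * max(1.0, abs(ll_prev)))
        )
    except np.linalg.LinAlgError:
        ok = False
    if ok:
        return b2, c2, p2, s2, ll2
    return beta, cov, psi, sig2, ll_prev


def _unpack(beta, layout, df, n_coh, O_base=None):
    intercept = float(beta[0])
    coefs = beta[1 : 1 + df].copy()
    O = np.zeros((n_coh, 3)) if O_base is None else O_base.copy()
    se_layout = {}
    for col, (c, j) in enumerate(layout, start=1 + df):
        O[c, j] = beta[col]
        se_layout[(c, j)] = col
    return intercept, coefs, O, se_layout


# ---------------------------------------------------------------------------
# log-likelihood at a parameter set (Laplace / FOCE-style)
# ---------------------------------------------------------------------------

def _laplace_ll(data, spec, intercept, coefs, O, psi_a, sig2, config, active, U0=None):
    """Approximate marginal log-likelihood at fixed parameters.

    The subject random effects are set to their penalized optimum
    (Gauss-Newton) and the Laplace determinant uses the Gauss-Newton
    Hessian, matching the linearized-model likelihood at the mode.
    """
    U = np.zeros((data.n_subj, 3)) if U0 is None else U0
    U = _inner_gn(data, spec, intercept, coefs, O, psi_a, sig2, U, active)
    X, Z, w, beta, _ = _design(data, spec, intercept, coefs, O, U, config, active)
    st = _lin_stats(data, X, Z, w, beta, psi_a, sig2)
    return st["ll"], U


def marginal_loglik(fit: SitarFit, records: list[MeasurementRecord]) -> float:
    """Laplace-approximate marginal log-likelihood of ``records`` under ``fit``.

    Deterministic given its inputs; the random effects are re-optimized
    from zero for the supplied records.  A non-positive-semidefinite
    random-effect covariance is rejected.
    """
    config = fit.config
    data = _Data(records, config, center=fit.age_center)
    active = tuple(RE_NAMES.index(n) for n in config.active_random_effects)
    psi_a = fit.re_cov[np.ix_(active, active)]
    lam = np.linalg.eigvalsh(psi_a)
    if lam.min() < -1e-10 * max(1.0, abs(lam).max()):
        raise ValueError("random-effect covariance proposal is not positive semidefinite")
    sig2 = np.array(
        [fit.residual_sd[c] ** 2 for c in data.cohort_ids]
    )
    O = np.zeros((data.n_coh, 3))
    O[0, 1], O[0, 2] = fit.global_shift
    for c, cid in enumerate(data.cohort_ids):
        if c > 0 and cid in fit.cohort_offsets:
            O[c] = fit.cohort_offsets[cid]
    ll, _ = _laplace_ll(
        data, fit.spline_spec, fit.intercept, fit.spline_coefs, O,
        psi_a, sig2, config, active,
    )
    return float(ll)


# ---------------------------------------------------------------------------
# main fitting routine
# ---------------------------------------------------------------------------

def fit_sitar(records: list[MeasurementRecord], config: SitarConfig) -> SitarFit:
    """Fit the shape-invariant growth model by approximate maximum likelihood.

    ``records`` must cover a single trait and sex (the full analysis runs
    four separate fits).  Returns a :class:`SitarFit`; ``converged`` is
    False when the outer loop exhausted ``config.max_iter`` without the
    log-likelihood stabilizing to ``config.tol`` (relative).
    """
    data = _Data(records, config)
    if data.n_subj < 30:
        raise ValueError(f"need at least 30 subjects, got {data.n_subj}")
    active = tuple(RE_NAMES.index(n) for n in config.active_random_effects)
    if not active:
        raise ValueError("at least one random effect must be active")
    k = len(active)
    if data.obs_per_subject.max() < k:
        raise ValueError(
            f"{k} random effects requested but every subject has fewer than "
            f"{k} observations; the model is not identifiable"
        )

    # spline spec and OLS initialization; an explicit user spec is given on
    # the plain transformed-age scale and shifted onto the centered scale
    spec = config.spline_spec
    if spec is None:
        spec = spl.make_spline_spec(data.t, config.df)
    else:
        c = data.center
        spec = spl.SplineSpec(
            boundary_knots=(spec.boundary_knots[0] - c, spec.boundary_knots[1] - c),
            interior_knots=tuple(k - c for k in spec.interior_knots),
            df=spec.df,
        )
    B0 = spl.basis(spec, data.t)
    X0 = np.column_stack([np.ones(data.n), B0])
    coef0, *_ = np.linalg.lstsq(X0, data.y, rcond=None)
    intercept, coefs = float(coef0[0]), coef0[1:]
    resid0 = data.y - X0 @ coef0

    if config.per_cohort_residual:
        sig2 = np.array([
            max(np.var(resid0[data.coh == c]), 1e-12) for c in range(data.n_coh)
        ])
    else:
        sig2 = np.full(data.n_coh, max(np.var(resid0), 1e-12))

    var_y = float(np.var(data.y))
    psi_full_init = np.diag([_INIT_SIZE_VAR_FRAC * var_y, _INIT_TV_VAR, _INIT_TV_VAR])
    psi_a = psi_full_init[np.ix_(active, active)].copy()

    O = np.zeros((data.n_coh, 3))
    U = np.zeros((data.n_subj, 3))
    layout, p = _pack_layout(data, config, spec.df, active)

    ll_old = None
    ll_trace: list[float] = []
    converged = False
    n_iter = 0
    se_layout: dict = {}
    cov_beta = np.eye(p)
    tiny = 1e-12

    def _pnls_q(ib, cb, Ob, U_, psi_inv_):
        """Exact penalized least-squares objective at fixed variances."""
        f, *_ = _terms(spec, float(ib), cb, Ob, U_, data)
        res = data.y - f
        q = float(np.sum(res * res / sig2[data.coh]))
        Ua_ = U_[:, active]
        q += float(np.einsum("si,ij,sj->", Ua_, psi_inv_, Ua_))
        return q

    def _profile(ib, cb, U_, O_, psi_inv_, max_alt=15, rtol=1e-10,
                 inner_iter=12):
        """Optimize intercept, spline coefficients, global tempo/velocity
        shifts and random effects at fixed cohort contrasts and variances
        (alternating damped GLS and per-subject Gauss-Newton)."""
        q_prev = None
        q_cur_ = None
        O_ = O_.copy()
        for _ in range(max_alt):
            U_ = _inner_gn(data, spec, ib, cb, O_, psi_a, sig2, U_, active,
                           max_iter=inner_iter)
            X_, Z_, w_, beta_cur_, layout0 = _design(
                data, spec, ib, cb, O_, U_, config, active, include_offsets=False
            )
            A_, b_ = _gls_system(data, X_, Z_, w_, psi_a, sig2)
            try:
                beta_new_ = np.linalg.solve(A_, b_)
            except np.linalg.LinAlgError as exc:
                raise ValueError("rank-deficient spline design") from exc
            q_base = _pnls_q(ib, cb, O_, U_, psi_inv_)
            lam_ = 1.0
            q_cur_ = q_base
            for _h in range(12):
                cand = beta_cur_ + lam_ * (beta_new_ - beta_cur_)
                ib_t, cb_t, O_t, _ = _unpack(cand, layout0, spec.df, data.n_coh,
                                             O_base=O_)
                U_t = _inner_gn(data, spec, ib_t, cb_t, O_t, psi_a, sig2, U_,
                                active, max_iter=inner_iter)
                q_t = _pnls_q(ib_t, cb_t, O_t, U_t, psi_inv_)
                if np.isfinite(q_t) and q_t <= q_base * (1.0 + tiny):
                    ib, cb, O_, U_, q_cur_ = ib_t, cb_t, O_t, U_t, q_t
                    break
                lam_ *= 0.5
            if q_prev is not None and q_prev - q_cur_ <= rtol * max(1.0, q_cur_):
                break
            q_prev = q_cur_
        return ib, cb, O_, U_, q_cur_

    n_contrasts = sum(1 for (c, j) in layout if c > 0)
    for it in range(config.max_iter):
        n_iter = it + 1
        psi_inv, _ = _psi_inv(psi_a)
        # --- PNLS step: intercept, spline, global shifts and random
        # effects by alternating damped GLS / per-subject Gauss-Newton;
        # cohort contrasts pick up the per-cohort means of the random
        # effects through the recentring transfer ---
        intercept, coefs, O, U, q_cur = _profile(intercept, coefs, U, O, psi_inv)
        intercept = _recentre(data, config, active, intercept, O, U)

        # --- LME step: full ML solve of the linearized mixed model
        # (variance components to convergence on the fixed pseudo-data) ---
        X, Z, w, beta_cur, layout = _design(
            data, spec, intercept, coefs, O, U, config, active
        )
        beta_lme, cov_lme, psi_a, sig2, ll_cur = _lme_solve(
            data, X, Z, w, psi_a, sig2, config.per_cohort_residual, max_em=300
        )
        ll_lap, U = _laplace_ll(
            data, spec, intercept, coefs, O, psi_a, sig2, config, active, U0=U
        )
        ll_trace.append(float(ll_lap))
        if _DEBUG:
            print(f"  outer {it}: q={q_cur:.3f} ll={ll_lap:.3f} "
                  f"O1={np.round(O[1] if data.n_coh > 1 else O[0], 4)} "
                  f"psi_sd={np.round(np.sqrt(np.maximum(np.diag(psi_a), 0)), 4)} "
                  f"sig={np.round(np.sqrt(sig2), 3)}")
        # with cohort contrasts in the model the alternation enters a slow
        # drift regime (contrasts creep via the recentring transfer); hand
        # over to the Newton polish below once gains are modest
        stage_tol = config.tol if n_contrasts == 0 else max(config.tol, 1e-4)
        if ll_old is not None and abs(ll_lap - ll_old) <= stage_tol * max(1.0, abs(ll_old)):
            converged = True
            ll_old = ll_lap
            break
        ll_old = ll_lap

    # --- offset polish: the alternation estimates the offsets against the
    # penalized least-squares objective, which omits the determinant term
    # of the Laplace likelihood and attenuates the offsets when subjects
    # carry few observations.  A few damped Newton steps directly on the
    # Laplace objective (finite-difference gradient over the offset block,
    # Schur-complement Hessian) remove that bias. ---
    if n_contrasts:
        p0 = 1 + spec.df + (len(layout) - n_contrasts)
        lm_lambda = 1e-2
        for _polish in range(8):
            psi_inv, _ = _psi_inv(psi_a)
            ll_cur, U = _laplace_ll(
                data, spec, intercept, coefs, O, psi_a, sig2, config, active, U0=U
            )
            X, Z, w, beta_cur, layout = _design(
                data, spec, intercept, coefs, O, U, config, active
            )
            A, bvec = _gls_system(data, X, Z, w, psi_a, sig2)
            try:
                cov_beta = np.linalg.inv(A)
                sol_x = np.linalg.solve(A[:p0, :p0], A[:p0, p0:])
            except np.linalg.LinAlgError as exc:
                raise ValueError("rank-deficient fixed-effect design") from exc
            Schur = A[p0:, p0:] - A[:p0, p0:].T @ sol_x
            dS = np.maximum(np.diag(Schur), 1e-12 * max(np.diag(Schur).max(), 1.0))
            contrast_layout = [e for e in layout if e[0] > 0]
            g_lap = np.empty(len(contrast_layout))
            for col, (c, j) in enumerate(contrast_layout):
                h = 0.1 / np.sqrt(dS[col])
                Op = O.copy(); Op[c, j] += h
                Om = O.copy(); Om[c, j] -= h
                lp, _ = _laplace_ll(data, spec, intercept, coefs, Op, psi_a,
                                    sig2, config, active, U0=U)
                lmn, _ = _laplace_ll(data, spec, intercept, coefs, Om, psi_a,
                                     sig2, config, active, U0=U)
                g_lap[col] = (lp - lmn) / (2 * h)
            moved = False
            for _try in range(10):
                try:
                    d_off = np.linalg.solve(Schur + lm_lambda * np.diag(dS), g_lap)
                except np.linalg.LinAlgError:
                    break
                O_try = O.copy()
                for col, (c, j) in enumerate(contrast_layout):
                    O_try[c, j] += d_off[col]
                ll_try, U_try = _laplace_ll(
                    data, spec, intercept, coefs, O_try, psi_a, sig2, config,
                    active, U0=U,
                )
                if np.isfinite(ll_try) and ll_try > ll_cur + 1e-12 * max(1.0, abs(ll_cur)):
                    gain = ll_try - ll_cur
                    O, U, ll_cur = O_try, U_try, ll_try
                    lm_lambda = max(1e-8, lm_lambda / 3.0)
                    moved = True
                    break
                lm_lambda = min(1e8, lm_lambda * 10.0)
            if not moved:
                converged = True
                break
            # re-profile the spline/random effects and re-solve variances
            intercept, coefs, O, U, _ = _profile(intercept, coefs, U, O, psi_inv, max_alt=8)
            intercept = _recentre(data, config, active, intercept, O, U)
            X, Z, w, beta_cur, layout = _design(
                data, spec, intercept, coefs, O, U, config, active
            )
            _, cov_beta, psi_a, sig2, _ = _lme_solve(
                data, X, Z, w, psi_a, sig2, config.per_cohort_residual, max_em=150
            )
            if gain <= 10 * config.tol * max(1.0, abs(ll_cur)):
                converged = True
                break
        else:
            converged = False

    # final random effects at the accepted parameters, recentred so the
    # reported BLUPs are mean zero
    U = _inner_gn(data, spec, intercept, coefs, O, psi_a, sig2, U, active)
    intercept = _recentre(data, config, active, intercept, O, U)

    # fixed-effect covariance at the solution (Wald standard errors)
    X, Z, w, beta_cur, layout = _design(
        data, spec, intercept, coefs, O, U, config, active
    )
    A_fin, _b_fin = _gls_system(data, X, Z, w, psi_a, sig2)
    try:
        cov_beta = np.linalg.inv(A_fin)
    except np.linalg.LinAlgError:
        pass
    se_layout = {(c, j): col + 1 + spec.df for col, (c, j) in enumerate(layout)}
    ll_final, _ = _laplace_ll(
        data, spec, intercept, coefs, O, psi_a, sig2, config, active, U0=U
    )

    re_cov = np.zeros((3, 3))
    re_cov[np.ix_(active, active)] = psi_a
    blups = [
        RandomEffects(subject_id=sid, size=float(U[s, 0]), tempo=float(U[s, 1]),
                      velocity=float(U[s, 2]))
        for s, sid in enumerate(data.subjects)
    ]
    offsets = {}
    offset_se = {}
    for c, cid in enumerate(data.cohort_ids):
        offsets[cid] = O[c].copy() if c > 0 else np.zeros(3)
        se = np.full(3, np.nan)
        if c > 0:
            for j in range(3):
                col = se_layout.get((c, j))
                if col is not None:
                    se[j] = np.sqrt(max(cov_beta[col, col], 0.0))
        else:
            se[:] = 0.0
        offset_se[cid] = se

    fit = SitarFit(
        trait=data.trait,
        sex=data.sex,
        config=config,
        spline_spec=spec,
        intercept=intercept,
        spline_coefs=np.asarray(coefs, dtype=float),
        cohort_ids=list(data.cohort_ids),
        cohort_offsets=offsets,
        offset_se=offset_se,
        re_cov=re_cov,
        residual_sd={cid: float(np.sqrt(sig2[c])) for c, cid in enumerate(data.cohort_ids)},
        blups=blups,
        subject_cohorts={
            sid: data.cohort_ids[data.subj_coh[s]] for s, sid in enumerate(data.subjects)
        },
        loglik=float(ll_final),
        converged=converged,
        n_iter=n_iter,
        geometric_mean_age=data.geometric_mean_age,
        age_center=data.center,
        n_subjects=data.n_subj,
        n_records=data.n,
        ll_trace=ll_trace,
        global_shift=(float(O[0, 1]), float(O[0, 2])),
    )
    logger.info(
        "fit %s/%s: %d subjects, %d records, loglik %.3f, %d iterations, converged=%s",
        fit.trait, fit.sex, fit.n_subjects, fit.n_records, fit.loglik, n_iter, converged,
    )
    return fit


# ---------------------------------------------------------------------------
# prediction and summaries
# ---------------------------------------------------------------------------

def _subject_effects(fit: SitarFit, subject_or_mean) -> np.ndarray:
    if subject_or_mean is None or subject_or_mean == "mean":
        return np.zeros(3)
    if isinstance(subject_or_mean, RandomEffects):
        return subject_or_mean.as_array()
    for b in fit.blups:
        if b.subject_id == subject_or_mean:
            return b.as_array()
    raise KeyError(f"subject {subject_or_mean!r} not in fit")


def _total_effects(fit: SitarFit, cohort_id, subject_or_mean) -> np.ndarray:
    eff = _subject_effects(fit, subject_or_mean)
    if cohort_id is None:
        cohort_id = fit.reference_cohort
    if cohort_id not in fit.cohort_offsets:
        raise KeyError(f"cohort {cohort_id!r} not in fit")
    b0, g0 = fit.global_shift
    return eff + fit.cohort_offsets[cohort_id] + np.array([0.0, b0, g0])


def _transform_age(fit: SitarFit, ages: np.ndarray) -> np.ndarray:
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    if np.any(ages <= 0):
        raise ValueError("ages must be positive")
    raw = np.log(ages) if fit.config.age_transform == "log" else ages
    return raw - fit.age_center


def predict_curve(fit: SitarFit, cohort_id=None, subject_or_mean=None, ages=None) -> np.ndarray:
    """Predicted trait values at ``ages`` (years).

    With ``subject_or_mean`` None (or "mean") and the reference cohort,
    this is the fitted mean curve; otherwise the subject's random
    effects and/or the cohort's fixed offsets are applied.
    """
    a, b, g = _total_effects(fit, cohort_id, subject_or_mean)
    t = _transform_age(fit, ages)
    u = np.exp(g) * (t - b)
    return fit.intercept + spl.basis(fit.spline_spec, u) @ fit.spline_coefs + a


def velocity_curve(fit: SitarFit, cohort_id=None, subject_or_mean=None, ages=None) -> np.ndarray:
    """Growth velocity dy/d(age) in trait units per year at ``ages``.

    Chain rule through the scaled transformed age: dy/dage =
    s'(u) * exp(g) * dt/dage, with dt/dage = 1/age under the log
    transform.
    """
    a, b, g = _total_effects(fit, cohort_id, subject_or_mean)
    ages_arr = np.atleast_1d(np.asarray(ages, dtype=float))
    t = _transform_age(fit, ages_arr)
    u = np.exp(g) * (t - b)
    sprime = spl.basis_derivative(fit.spline_spec, u) @ fit.spline_coefs
    dt_dage = 1.0 / ages_arr if fit.config.age_transform == "log" else np.ones_like(ages_arr)
    return sprime * np.exp(g) * dt_dage


def age_at_peak_velocity(fit: SitarFit, subject_or_mean=None, cohort_id=None,
                         window=(8.0, 16.0)) -> APVResult:
    """Age (years) maximizing the velocity curve within ``window``.

    A coarse grid locates the global peak's basin, then golden-section
    search refines it to 0.001 y.  When the maximum sits at the window
    edge (no interior peak), the result is flagged ``interior=False``.
    """
    from scipy.optimize import minimize_scalar

    lo, hi = window
    grid = np.linspace(lo, hi, 201)
    vg = velocity_curve(fit, cohort_id, subject_or_mean, grid)
    i0 = int(np.argmax(vg))
    blo = grid[max(i0 - 1, 0)]
    bhi = grid[min(i0 + 1, grid.size - 1)]
    if blo == bhi:
        blo, bhi = lo, hi
    res = minimize_scalar(
        lambda x: -float(velocity_curve(fit, cohort_id, subject_or_mean, np.array([x]))[0]),
        bounds=(blo, bhi), method="bounded", options={"xatol": 1e-4},
    )
    age = float(res.x)
    interior = (age - lo > 5e-3) and (hi - age > 5e-3)
    return APVResult(age=age, interior=interior)


def cohort_contrasts(fit: SitarFit, z: float = 1.959964) -> list[CohortContrast]:
    """Cohort fixed offsets in reporting units with Wald 95% CIs.

    Size stays in trait units; tempo is converted to years via the
    geometric mean age (under the log-age transform); velocity is
    reported as a percentage (100 x the log-scale stretch).
    """
    gma = fit.geometric_mean_age if fit.config.age_transform == "log" else 1.0
    out = []
    for cid in fit.cohort_ids:
        d = fit.cohort_offsets[cid]
        se = fit.offset_se[cid]
        se = np.where(np.isfinite(se), se, 0.0)
        out.append(
            CohortContrast(
                cohort_id=cid,
                trait=fit.trait,
                size_delta=float(d[0]),
                size_ci=(float(d[0] - z * se[0]), float(d[0] + z * se[0])),
                tempo_delta_years=float(d[1] * gma),
                tempo_ci=(float((d[1] - z * se[1]) * gma), float((d[1] + z * se[1]) * gma)),
                velocity_delta_pct=float(100 * d[2]),
                velocity_ci=(float(100 * (d[2] - z * se[2])), float(100 * (d[2] + z * se[2]))),
            )
        )
    return out


def summarize_random_effects(fit: SitarFit) -> dict:
    """Model-SD summary: residual SDs and random-effect SDs in reporting units.

    Tempo is reported both as a percentage (100 x log-age SD, a
    coefficient of variation) and in years (x geometric mean age);
    velocity as a percentage.
    """
    gma = fit.geometric_mean_age if fit.config.age_transform == "log" else 1.0
    sd = np.sqrt(np.clip(np.diag(fit.re_cov), 0.0, None))
    return {
        "residual_sd": dict(fit.residual_sd),
        "sd_size": float(sd[0]),
        "sd_tempo": float(sd[1]),
        "sd_tempo_pct": float(100 * sd[1]),
        "sd_tempo_years": float(sd[1] * gma),
        "sd_velocity": float(sd[2]),
        "sd_velocity_pct": float(100 * sd[2]),
        "geometric_mean_age": fit.geometric_mean_age,
    }


def export_curves(fit: SitarFit, ages: np.ndarray, path=None):
    """Mean and per-cohort fitted curves over an age grid, as a DataFrame/CSV."""
    import pandas as pd

    ages = np.asarray(ages, dtype=float)
    cols = {"age": ages}
    for cid in fit.cohort_ids:
        cols[f"curve_{cid}"] = predict_curve(fit, cohort_id=cid, ages=ages)
        cols[f"velocity_{cid}"] = velocity_curve(fit, cohort_id=cid, ages=ages)
    df = pd.DataFrame(cols)
    if path is not None:
        df.to_csv(path, index=False)
    return df
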