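"""Joint-SFS demographic inference for the nested three-population model.

Two nested models are fit by Poisson composite likelihood: isolation with
no migration, and isolation with symmetric migration, both under the
(WN, (EA, EB)) splitting order.  The expected joint SFS is computed by a
Monte-Carlo coalescent engine: branch lengths of simulated genealogies
are accumulated into SFS cells, so that cell expectation = (theta/2) x
mean accumulated length.  This replaces the Wright-Fisher diffusion
solver used by classical SFS tools — a deliberate methodological choice:
it is exact in expectation, testable against coalescent theory, and
shares its event engine with the data simulator.

The optimizer is a derivative-free Nelder-Mead search over
log10-transformed sizes, times and migration rates (the split-time order
T1 > T2 is enforced by searching over f = T2/T1), with common random
numbers: one fixed genealogy seed per optimization makes the Monte-Carlo
likelihood surface deterministic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from . import _coalescent
from .sfs import JointSFS, default_mask
from .simdata import DemographicParams

NO_MIGRATION = "no_migration"
SYMMETRIC_MIGRATION = "symmetric_migration"

_NU_NAMES = ("nu_WN", "nu_E", "nu_EA", "nu_EB")
_M_NAMES = ("M_WN_EA", "M_WN_EB", "M_EA_EB")

_BOUNDS = {"nu": (1e-3, 1e3), "T1": (1e-4, 5.0), "M": (1e-4, 20.0)}


@dataclass
class ScalingConstants:
    """Constants converting scaled estimates to real units: per-site
    per-generation mutation rate mu, generations per year g, and the
    total analyzed sequence length L in bp."""

    mu: float = 5.8e-9
    g: float = 10.0
    L: float = 1.0e6

    def validate(self):
        if min(self.mu, self.g, self.L) <= 0:
            raise ValueError("scaling constants must be positive")
        return self


@dataclass
class FitConfig:
    """Optimizer settings.

    ``n_genealogies`` sets the Monte-Carlo effort per likelihood
    evaluation in the multi-start coarse stage; each of ``polish_rounds``
    restarts from the best point then uses ``polish_genealogies``
    (default 10x) to shrink the Monte-Carlo roughness of the surface.
    ``seed`` drives both the start sampler and the common-random-numbers
    genealogy seeds, making the whole fit deterministic.
    """

    n_genealogies: int = 1000
    n_starts: int = 5
    maxiter: int = 500
    polish_genealogies: int = None
    polish_rounds: int = 2
    polish_maxiter: int = 300
    refine_rounds: int = 2
    refine_radius: float = 0.15
    simplex_spread: float = 0.3
    seed: int = 0
    free_m_wn_e: bool = False
    tie_nu_e: bool = False          # tie ancestral-Eastern size to nu_EA
    zero_floor: float = 1e-6
    bootstrap_starts: int = 2
    bootstrap_n_loci: int = 1000
    bootstrap_locus_length: int = 10_000

    def free_names(self, model):
        names = list(_NU_NAMES) + ["T1", "f"]
        if self.tie_nu_e:
            names.remove("nu_E")
        if model == SYMMETRIC_MIGRATION:
            names += list(_M_NAMES)
            if self.free_m_wn_e:
                names.append("M_WN_E")
        elif model != NO_MIGRATION:
            raise ValueError(f"unknown model {model!r}")
        return names


@dataclass
class FitResult:
    model: str
    params: DemographicParams
    theta_hat: float
    loglik: float
    free_names: list
    trace: list = field(default_factory=list)
    seed: int = 0
    data: JointSFS = None
    scaled: dict = None

    def free_values(self):
        vals = {n: getattr(self.params, n) for n in self.free_names if n != "f"}
        if "f" in self.free_names:
            vals["T2"] = self.params.T2
        vals["theta_hat"] = self.theta_hat
        return vals


@dataclass
class BootstrapResult:
    estimates: "object"           # DataFrame, one row per successful replicate
    ci: "object"                  # DataFrame with rows lower/upper (2.5/97.5%)
    sd: "object"                  # Series of per-parameter SDs
    n_reps: int
    n_failed: int
    seeds: list


def expected_sfs(params: DemographicParams, sample_sizes, n_genealogies,
                 seed) -> np.ndarray:
    """Per-unit-theta expected joint SFS (chromosome sample sizes).

    Entry [i, j, k] is half the mean accumulated branch length for the
    (i, j, k) descendant configuration, so that expected site count =
    theta x value.  Deterministic given ``seed``.
    """
    acc = _coalescent.accumulate_branch_lengths(
        params, sample_sizes, n_genealogies, seed)
    return acc / 2.0


def simulate_sfs_data(params: DemographicParams, theta_total, n_loci,
                      sample_sizes, seed, pops=("WN", "EA", "EB")) -> JointSFS:
    """Draw one finite dataset's joint SFS under the model.

    Simulates ``n_loci`` independent genealogies and drops infinite-sites
    mutations as a Poisson process: the site count of each SFS cell is
    Poisson with mean (theta_total / n_loci / 2) x total accumulated
    branch length for that cell.
    """
    acc = _coalescent.accumulate_branch_lengths(
        params, sample_sizes, n_loci, seed) * n_loci
    rng = np.random.default_rng(seed)
    data = rng.poisson(theta_total / n_loci / 2.0 * acc).astype(float)
    mask = default_mask(data.shape)
    data[mask] = 0.0
    return JointSFS(data, pops)


def composite_loglik(data: JointSFS, model_per_theta, zero_floor=1e-6):
    """Poisson composite log-likelihood with the analytic theta optimum.

    theta_hat = sum(D) / sum(m) over unmasked cells; loglik =
    sum[D*ln(theta_hat*m) - theta_hat*m] over unmasked cells with m > 0,
    dropping the log D! constant.  Cells with m = 0 but D > 0 contribute
    through a floor of ``zero_floor`` in place of m.
    """
    m = model_per_theta.data if isinstance(model_per_theta, JointSFS) \
        else np.asarray(model_per_theta)
    if m.shape != data.data.shape:
        raise ValueError("data and model shapes differ")
    unmasked = ~data.mask
    D = data.data[unmasked]
    mm = m[unmasked]
    msum = mm.sum()
    if msum <= 0:
        raise ValueError("model spectrum has no unmasked mass")
    theta_hat = D.sum() / msum
    # floor only where the model predicts nothing but data were observed
    mm = np.where((mm <= 0) & (D > 0), zero_floor, mm)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(D > 0, D * np.log(theta_hat * mm), 0.0) - theta_hat * mm
    return float(terms.sum()), float(theta_hat)


def _pack(values: dict, names):
    x = []
    for n in names:
        v = values[n]
        if n == "f":
            v = min(max(v, 1e-6), 1 - 1e-6)
            x.append(np.log(v / (1 - v)))
        else:
            if n.startswith("M"):
                v = max(v, _BOUNDS["M"][0])  # M=0 sits at the lower bound
            x.append(np.log10(v))
    return np.array(x)


def _unpack(x, names):
    values, penalty = {}, 0.0
    for xi, n in zip(x, names):
        if n == "f":
            values[n] = 1.0 / (1.0 + np.exp(-xi))
            continue
        lo, hi = _BOUNDS["T1"] if n == "T1" else (
            _BOUNDS["M"] if n.startswith("M") else _BOUNDS["nu"])
        lo10, hi10 = np.log10(lo), np.log10(hi)
        if xi <= lo10 and n.startswith("M"):
            # the migration lower bound is an exact zero, so the
            # no-migration model is nested inside the search space
            values[n] = 0.0
            continue
        if xi < lo10:
            penalty += (lo10 - xi) ** 2
            xi = lo10
        elif xi > hi10:
            penalty += (xi - hi10) ** 2
            xi = hi10
        values[n] = 10.0 ** xi
    return values, penalty


def _to_params(values, model, config):
    kw = {n: v for n, v in values.items() if n not in ("f",)}
    T1 = kw.pop("T1")
    kw["T1"] = T1
    kw["T2"] = values["f"] * T1
    if config.tie_nu_e:
        kw["nu_E"] = kw["nu_EA"]
    if model == NO_MIGRATION:
        for n in _M_NAMES + ("M_WN_E",):
            kw[n] = 0.0
    else:
        if not config.free_m_wn_e:
            kw["M_WN_E"] = 0.0
    return DemographicParams(**kw)


_DEFAULT_GUESS = {"nu_WN": 1.0, "nu_E": 1.0, "nu_EA": 1.0, "nu_EB": 1.0,
                  "T1": 0.2, "f": 0.4, "M_WN_EA": 0.3, "M_WN_EB": 0.3,
                  "M_EA_EB": 0.3, "M_WN_E": 0.3}


def _quadratic_refine(objective, x0, radius, rng, n_points=None):
    """One round of response-surface refinement.

    Samples points uniformly in a box of half-width ``radius`` around
    ``x0``, fits a full quadratic by least squares, and returns the
    quadratic's minimizer (eigenvalues floored, step clipped to the
    box).  Because the regression averages the Monte-Carlo noise over
    all sampled points, it locates the smooth surface's optimum far more
    efficiently than a simplex reacting to single noisy evaluations.
    The radius must stay large enough that the quadratic signal (which
    scales with radius^2) dominates the evaluation noise.
    """
    import itertools

    d = len(x0)
    pairs = list(itertools.combinations_with_replacement(range(d), 2))
    n_coef = 1 + d + len(pairs)
    n_points = n_points or int(2.5 * n_coef)
    Z = rng.uniform(-1, 1, size=(n_points, d))
    y = np.array([objective(x0 + radius * z) for z in Z])
    cols = [np.ones(n_points)] + [Z[:, i] for i in range(d)]
    cols += [Z[:, i] * Z[:, j] for i, j in pairs]
    coef, *_ = np.linalg.lstsq(np.column_stack(cols), y, rcond=None)
    b = coef[1:1 + d]
    H = np.zeros((d, d))
    for c, (i, j) in zip(coef[1 + d:], pairs):
        if i == j:
            H[i, i] = 2 * c
        else:
            H[i, j] = H[j, i] = c
    w, V = np.linalg.eigh(H)
    w = np.maximum(w, 1e-6)
    z = np.clip(-V @ ((V.T @ b) / w), -1, 1)
    return x0 + radius * z


def _nelder_mead(objective, x0, spread, maxiter):
    n = len(x0)
    simplex = np.vstack([x0] + [x0 + spread * np.eye(n)[i] for i in range(n)])
    return optimize.minimize(
        objective, x0, method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 0.5,
                 "adaptive": True, "initial_simplex": simplex})


def fit_demography(data: JointSFS, model: str, config: FitConfig = None,
                   initial: dict = None) -> FitResult:
    """Maximize the composite likelihood for one model.

    Coarse stage: ``config.n_starts`` Nelder-Mead searches from seeded
    random perturbations of the initial guess (each coordinate multiplied
    by up to ~10^0.5), with a wide initial simplex and a fixed genealogy
    seed shared by every evaluation so the Monte-Carlo surface is
    deterministic.  Polish stage: ``config.polish_rounds`` restarts from
    the best point at ~10x the genealogy count with a shrinking simplex,
    which removes most of the Monte-Carlo roughness that can trap the
    simplex.  Returns the best point with the full per-stage trace.
    """
    config = config or FitConfig()
    names = config.free_names(model)
    sizes = data.sample_sizes
    rng = np.random.default_rng(config.seed)
    crn_seed = int(rng.integers(2**31 - 1))
    polish_seed = int(rng.integers(2**31 - 1))
    n_polish = config.polish_genealogies or 10 * config.n_genealogies
    guess = dict(_DEFAULT_GUESS)
    if initial:
        guess.update(initial)
    x0 = _pack(guess, names)

    def make_objective(n_gen, seed):
        def objective(x):
            values, penalty = _unpack(x, names)
            params = _to_params(values, model, config)
            m = expected_sfs(params, sizes, n_gen, seed)
            ll, _ = composite_loglik(data, m, config.zero_floor)
            return -ll + 1e6 * penalty
        return objective

    coarse = make_objective(config.n_genealogies, crn_seed)
    trace, best = [], None
    for start in range(config.n_starts):
        x_start = x0 if start == 0 else x0 + rng.uniform(-0.5, 0.5, size=len(names))
        res = _nelder_mead(coarse, x_start, config.simplex_spread,
                           config.maxiter)
        trace.append({"stage": "coarse", "start": start,
                      "x0": x_start.tolist(), "fun": float(res.fun),
                      "nit": int(res.nit),
                      "converged": bool(np.isfinite(res.fun)),
                      "seed": crn_seed})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError("no optimizer start produced a finite likelihood")

    polish = make_objective(n_polish, polish_seed)
    spread = config.simplex_spread / 3.0
    best_x, best_fun = best.x, np.inf
    for round_ in range(config.polish_rounds):
        res = _nelder_mead(polish, best_x, spread, config.polish_maxiter)
        trace.append({"stage": "polish", "start": round_, "fun": float(res.fun),
                      "nit": int(res.nit),
                      "converged": bool(np.isfinite(res.fun)),
                      "seed": polish_seed})
        if np.isfinite(res.fun) and res.fun < best_fun:
            best_x, best_fun = res.x, res.fun
        spread /= 2.0
    for round_ in range(config.refine_rounds):
        radius = config.refine_radius / (1.2 ** round_)
        cand = _quadratic_refine(polish, best_x, radius, rng)
        # guarded step: the quadratic can extrapolate wildly along weakly
        # identified ridges, so the candidate must beat the incumbent in
        # a paired comparison on fresh surfaces — judging on the polish
        # surface itself would always favor its own argmin
        cmp_seeds = [int(rng.integers(2**31 - 1)) for _ in range(2)]
        fun_cand = fun_inc = 0.0
        for s in cmp_seeds:
            obj_cmp = make_objective(n_polish, s)
            fun_cand += obj_cmp(cand)
            fun_inc += obj_cmp(best_x)
        accepted = np.isfinite(fun_cand) and fun_cand < fun_inc
        trace.append({"stage": "refine", "start": round_,
                      "fun": float(fun_cand / 2), "nit": 0,
                      "converged": accepted, "seed": polish_seed})
        if accepted:
            best_x = cand
    # a supplied initial point is kept as a candidate on the polish
    # surface, so seeding with a nested model's optimum can never lose it
    if initial is not None and polish(x0) < polish(best_x):
        best_x = x0

    values, _ = _unpack(best_x, names)
    params = _to_params(values, model, config)
    m = expected_sfs(params, sizes, n_polish, polish_seed)
    ll, theta_hat = composite_loglik(data, m, config.zero_floor)
    return FitResult(model, params, theta_hat, ll, names, trace,
                     seed=crn_seed, data=data)


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float
    note: str = ("composite-likelihood LRT: p-values are anti-conservative "
                 "because sites are not independent")


def likelihood_ratio_test(fit_null: FitResult, fit_alt: FitResult) -> LRTResult:
    """2*(ll_alt - ll_null), clamped at zero, against chi-square with df =
    number of freed migration parameters."""
    if not (fit_null.model == NO_MIGRATION
            and fit_alt.model == SYMMETRIC_MIGRATION):
        raise ValueError("LRT requires a no-migration null nested in a "
                         "symmetric-migration alternative")
    df = sum(1 for n in fit_alt.free_names if n.startswith("M"))
    stat = max(0.0, 2.0 * (fit_alt.loglik - fit_null.loglik))
    return LRTResult(stat, df, float(stats.chi2.sf(stat, df)))


def parametric_bootstrap(fit: FitResult, n_reps: int = 100,
                         config: FitConfig = None) -> BootstrapResult:
    """Empirical CIs by simulate-at-the-MLE, then re-analyze.

    Each replicate simulates a finite dataset (``config.bootstrap_n_loci``
    loci) at the fitted parameters and theta, rebuilds the joint SFS and
    re-runs the same fitting procedure (same model, same start scheme).
    Re-analyzing from scratch rather than hot-starting at the MLE keeps
    optimizer variability inside the replicate dispersion, so percentile
    CIs reflect the estimator as actually used.  ``bootstrap_starts``
    can lower the per-replicate start count (0 keeps the original
    fit's).  Returns percentile 2.5/97.5 bounds and SDs per free
    parameter; replicates with no finite-likelihood fit are excluded and
    counted, more than 20% failures aborts.
    """
    import pandas as pd

    config = config or FitConfig()
    if fit.data is None:
        raise ValueError("fit carries no data (needed for sample sizes)")
    sizes = fit.data.sample_sizes
    rng = np.random.default_rng(config.seed + 1)
    boot_cfg = dataclasses.replace(
        config, n_starts=config.bootstrap_starts or config.n_starts)

    rows, seeds, failed = [], [], 0
    for rep in range(n_reps):
        rep_seed = int(rng.integers(2**31 - 1))
        seeds.append(rep_seed)
        sim = simulate_sfs_data(fit.params, fit.theta_hat,
                                config.bootstrap_n_loci, sizes, rep_seed,
                                pops=fit.data.pops)
        try:
            refit = fit_demography(
                sim, fit.model, dataclasses.replace(boot_cfg, seed=rep_seed))
        except RuntimeError:
            failed += 1
            continue
        rows.append(refit.free_values())
    if failed > 0.2 * n_reps:
        raise RuntimeError(f"{failed}/{n_reps} bootstrap replicates failed")

    est = pd.DataFrame(rows)
    ci = pd.DataFrame({c: np.percentile(est[c], [2.5, 97.5]) for c in est},
                      index=["lower", "upper"])
    return BootstrapResult(est, ci, est.std(ddof=1), n_reps, failed, seeds)


def scale_parameters(fit: FitResult, sc: ScalingConstants) -> FitResult:
    """Convert scaled MLEs to real units.

    N_ref = theta_hat / (4 mu L); N_i = nu_i N_ref individuals; split
    times in years = T x 2 N_ref / g; per-generation migration rates
    m = M / (4 N_ref) (M is on the 4 N_ref m scale used by the
    simulator).
    """
    sc.validate()
    n_ref = fit.theta_hat / (4.0 * sc.mu * sc.L)
    p = fit.params
    scaled = {"N_ref": n_ref,
              "N_WN": p.nu_WN * n_ref, "N_E": p.nu_E * n_ref,
              "N_EA": p.nu_EA * n_ref, "N_EB": p.nu_EB * n_ref,
              "T1_years": p.T1 * 2.0 * n_ref / sc.g,
              "T2_years": p.T2 * 2.0 * n_ref / sc.g,
              "m_WN_EA": p.M_WN_EA / (4.0 * n_ref),
              "m_WN_EB": p.M_WN_EB / (4.0 * n_ref),
              "m_EA_EB": p.M_EA_EB / (4.0 * n_ref),
              "m_WN_E": p.M_WN_E / (4.0 * n_ref)}
    return dataclasses.replace(fit, scaled=scaled)
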