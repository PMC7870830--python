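"""Phylogenetic generalized least squares of per-taxon slopes on traits.

The residual covariance across taxa reflects shared ancestry.  Three
covariance models are supported:

* **Brownian motion** — V_ij proportional to the shared root-to-MRCA path
  length t_ij;
* **Pagel's lambda** — Brownian off-diagonals scaled by lambda in [0, 1],
  interpolating between tip independence and full Brownian structure;
* **Ornstein-Uhlenbeck** (stationary, ultrametric trees) — correlations
  decay exponentially with patristic distance d_ij:
  V_ij = (1 / 2 alpha) * (1 - exp(-2 alpha T)) * exp(-alpha d_ij).

The overall rate sigma^2 is profiled out of the likelihood; lambda and
alpha are estimated by profile maximum likelihood on a grid refined by
golden-section search.  Model choice is by AIC; the trait effect is
tested with a GLS F-test of the trait model against the intercept-only
model under the same fitted covariance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

MODEL_KINDS = ("pagel_lambda", "brownian", "ornstein_uhlenbeck")
_GOLD = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class PGLSModel:
    kind: str
    lam: float | None = None
    alpha: float | None = None
    sigma2: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.lam is not None and self.kind != "pagel_lambda":
            raise ValueError("lambda applies only to the pagel_lambda model")
        if self.alpha is not None and self.kind != "ornstein_uhlenbeck":
            raise ValueError("alpha applies only to the ornstein_uhlenbeck model")


@dataclass
class PGLSFit:
    model: PGLSModel
    coefficients: dict[str, float]
    coef_se: dict[str, float]
    coef_cov: np.ndarray = field(repr=False)
    f_statistic: float
    p_value: float
    log_likelihood: float
    aic: float
    n: int
    n_params: int
    taxa: tuple[str, ...] = ()


def tree_structure(tree: dendropy.Tree, taxa: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Shared-path matrix C (root-to-MRCA depths) and patristic distances D.

    Rows/columns follow ``taxa`` order; raises if a taxon lacks a tip.
    """
    label_to_leaf = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    missing = sorted(set(taxa) - set(label_to_leaf))
    if missing:
        raise ValueError(f"tree is missing tips for taxa: {missing}")
    depths = {lab: label_to_leaf[lab].distance_from_root() for lab in taxa}
    pdm = tree.phylogenetic_distance_matrix()
    tax_objs = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(tax_objs[taxa[i]], tax_objs[taxa[j]])
    dep = np.array([depths[t] for t in taxa])
    # t_ij = (depth_i + depth_j - d_ij) / 2 gives the root-to-MRCA path
    C = (dep[:, None] + dep[None, :] - D) / 2.0
    np.fill_diagonal(C, dep)
    return C, D


def phylo_covariance(
    C: np.ndarray, D: np.ndarray, model: PGLSModel
) -> np.ndarray:
    """Unit-rate covariance matrix (sigma^2 profiled out) for one model."""
    if model.kind == "brownian":
        V = C.copy()
    elif model.kind == "pagel_lambda":
        if model.lam is None:
            raise ValueError("pagel_lambda covariance needs lam")
        V = model.lam * C
        np.fill_diagonal(V, np.diag(C))
    else:
        if model.alpha is None:
            raise ValueError("ornstein_uhlenbeck covariance needs alpha")
        depths = np.diag(C)
        if np.ptp(depths) > 1e-6 * max(depths.max(), 1.0):
            raise ValueError("OU covariance requires an ultrametric tree")
        T = float(depths.mean())
        a = model.alpha
        V = (1.0 / (2.0 * a)) * (1.0 - math.exp(-2.0 * a * T)) * np.exp(-a * D)
    _chol(V)  # raises on a genuinely bad matrix
    return V


def _chol(V: np.ndarray) -> np.ndarray:
    """Cholesky with a tiny escalating diagonal jitter.

    Very short branches can make the covariance numerically
    semi-definite; a ridge of at most 1e-8 of the mean diagonal is added
    before declaring the matrix invalid.
    """
    scale = float(np.mean(np.diag(V)))
    for jitter in (0.0, 1e-12, 1e-10, 1e-8):
        try:
            return np.linalg.cholesky(V + jitter * scale * np.eye(V.shape[0]))
        except np.linalg.LinAlgError:
            continue
    raise ValueError("covariance matrix not positive definite (bad branch lengths?)")


def _gls_profile(y: np.ndarray, X: np.ndarray, V: np.ndarray, reml: bool = False):
    """GLS with sigma^2 profiled: returns beta, loglik, sigma2_hat, extras.

    With ``reml`` the restricted likelihood is used (the fixed effects are
    integrated out), which markedly reduces the boundary bias of the
    profile estimates of lambda/alpha at small n.
    """
    n = y.size
    p = X.shape[1]
    L = _chol(V)
    yw = np.linalg.solve(L, y)
    Xw = np.linalg.solve(L, X)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    logdet = 2.0 * float(np.log(np.diag(L)).sum())
    XtX = Xw.T @ Xw
    if reml:
        sigma2 = rss / (n - p)
        loglik = -0.5 * (
            (n - p) * math.log(2.0 * math.pi * sigma2)
            + logdet
            + float(np.linalg.slogdet(XtX)[1])
            + (n - p)
        )
    else:
        sigma2 = rss / n
        loglik = -0.5 * (n * math.log(2.0 * math.pi * sigma2) + logdet + n)
    return beta, loglik, sigma2, rss, XtX, logdet


def _golden(f, lo: float, hi: float, tol: float = 1e-5) -> float:
    """Golden-section maximizer of f on [lo, hi]."""
    a, b = lo, hi
    c = b - _GOLD * (b - a)
    d = a + _GOLD * (b - a)
    fc, fd = f(c), f(d)
    while abs(b - a) > tol * max(1.0, abs(hi - lo)):
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - _GOLD * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLD * (b - a)
            fd = f(d)
    return (a + b) / 2.0


def pgls_fit(
    y,
    X,
    tree: dendropy.Tree,
    kind: str = "pagel_lambda",
    *,
    taxa: list[str],
    coef_names: list[str] | None = None,
    fixed_param: float | None = None,
    grid_size: int = 21,
    reml: bool = True,
) -> PGLSFit:
    """Fit a PGLS regression of y on X under one evolutionary covariance model.

    ``X`` must include the intercept column.  lambda (or the OU alpha) is
    estimated by maximizing the restricted profile likelihood (plain ML
    with ``reml=False``) unless ``fixed_param`` pins it.  The reported
    F-statistic compares the full design against intercept-only under the
    same fitted covariance; AIC counts regression coefficients, sigma^2
    and any estimated covariance parameter.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if y.size != n:
        raise ValueError("y and X have different numbers of taxa")
    if n <= p:
        raise ValueError(f"too few taxa (n={n}) for {p} design columns")
    for j in range(1, p):
        if np.ptp(X[:, j]) == 0:
            name = (coef_names or [f"x{k}" for k in range(p)])[j]
            raise ValueError(f"singular design: predictor {name!r} is constant")
    C, D = tree_structure(tree, list(taxa))

    estimated_extra = 0
    if kind == "brownian":
        model = PGLSModel(kind="brownian")
        V = phylo_covariance(C, D, model)
    elif kind == "pagel_lambda":
        if fixed_param is not None:
            lam = float(fixed_param)
        else:
            def ll(lam: float) -> float:
                Vl = lam * C
                np.fill_diagonal(Vl, np.diag(C))
                return _gls_profile(y, X, Vl, reml)[1]

            grid = np.linspace(0.0, 1.0, grid_size)
            best = grid[int(np.argmax([ll(g) for g in grid]))]
            lo = max(0.0, best - 1.0 / (grid_size - 1))
            hi = min(1.0, best + 1.0 / (grid_size - 1))
            lam = _golden(ll, lo, hi)
            # the boundary values are legitimate optima; keep whichever wins
            for cand in (0.0, 1.0):
                if ll(cand) > ll(lam):
                    lam = cand
            estimated_extra = 1
        model = PGLSModel(kind="pagel_lambda", lam=float(lam))
        V = phylo_covariance(C, D, model)
    elif kind == "ornstein_uhlenbeck":
        depth = float(np.diag(C).mean())
        lo_a, hi_a = 1e-6, 50.0 / depth
        if fixed_param is not None:
            alpha = float(fixed_param)
        else:
            # As alpha -> 0 the stationary OU covariance tends to a singular
            # equicorrelation matrix and the profile likelihood spikes
            # spuriously; ill-conditioned covariances are excluded from the
            # search.
            def ll_a(a: float) -> float:
                m = PGLSModel(kind="ornstein_uhlenbeck", alpha=a)
                Va = phylo_covariance(C, D, m)
                if np.linalg.cond(Va) > 1e7:
                    return -np.inf
                return _gls_profile(y, X, Va, reml)[1]

            grid = np.geomspace(lo_a, hi_a, grid_size)
            grid_ll = [ll_a(g) for g in grid]
            if not np.isfinite(max(grid_ll)):
                raise ValueError("OU covariance ill-conditioned over the whole alpha range")
            best = grid[int(np.argmax(grid_ll))]
            lg = np.log(grid)
            step = lg[1] - lg[0]

            def ll_log(t: float) -> float:
                return ll_a(math.exp(t))

            alpha = math.exp(
                _golden(ll_log, math.log(best) - step, min(math.log(best) + step, math.log(hi_a)))
            )
            estimated_extra = 1
        model = PGLSModel(kind="ornstein_uhlenbeck", alpha=float(alpha))
        V = phylo_covariance(C, D, model)
    else:
        raise ValueError(f"unknown model kind {kind!r}")

    beta, loglik, sigma2, rss, XtX, _ = _gls_profile(y, X, V, reml)
    model = PGLSModel(
        kind=model.kind, lam=model.lam, alpha=model.alpha, sigma2=float(sigma2)
    )
    # F-test: full design vs intercept-only under the same V
    beta0, _, _, rss0, _, _ = _gls_profile(y, X[:, :1], V)
    q = p - 1
    if q > 0 and rss > 0:
        f_stat = ((rss0 - rss) / q) / (rss / (n - p))
        p_val = float(stats.f.sf(f_stat, q, n - p))
    elif q > 0:
        f_stat, p_val = float("inf"), 0.0
    else:
        f_stat, p_val = float("nan"), float("nan")
    k = p + 1 + estimated_extra
    aic = 2.0 * k - 2.0 * loglik
    s2_unbiased = rss / (n - p)
    cov_beta = s2_unbiased * np.linalg.inv(XtX)
    names = coef_names or [f"x{j}" for j in range(p)]
    return PGLSFit(
        model=model,
        coefficients={nm: float(b) for nm, b in zip(names, beta)},
        coef_se={nm: float(math.sqrt(cov_beta[j, j])) for j, nm in enumerate(names)},
        coef_cov=cov_beta,
        f_statistic=float(f_stat),
        p_value=p_val,
        log_likelihood=float(loglik),
        aic=float(aic),
        n=n,
        n_params=k,
        taxa=tuple(taxa),
    )


def select_model(fits: list[PGLSFit]) -> PGLSFit:
    """Minimum-AIC fit; AIC ties broken toward fewer parameters."""
    ok = [f for f in fits if np.isfinite(f.aic)]
    if not ok:
        raise ValueError("no converged PGLS fit to select from")
    return min(ok, key=lambda f: (round(f.aic, 9), f.n_params))


def expand_tree_for_entities(
    tree: dendropy.Tree, entity_tip: dict[str, str], epsilon_frac: float = 1e-6
) -> dendropy.Tree:
    """Clone the tree, giving tips that host several analysis entities one
    near-zero-length daughter branch per entity.

    Used when two sexes of one species are analysed as separate entities
    sharing one phylogenetic position.  The daughter branch length is
    ``epsilon_frac`` times the tree depth (exactly zero would make the
    Brownian covariance singular).
    """
    tree = tree.clone(depth=1)
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    eps = epsilon_frac * depth
    by_tip: dict[str, list[str]] = {}
    for entity, tip in entity_tip.items():
        by_tip.setdefault(tip, []).append(entity)
    tns = tree.taxon_namespace
    for tip_label, entities in by_tip.items():
        leaf = next(
            (lf for lf in tree.leaf_node_iter() if lf.taxon.label == tip_label), None
        )
        if leaf is None:
            raise ValueError(f"tree is missing tip {tip_label!r}")
        if len(entities) == 1 and entities[0] == tip_label:
            continue
        leaf.taxon = None
        if leaf.edge.length is not None and leaf.edge.length > eps:
            leaf.edge.length -= eps
        for entity in entities:
            child = leaf.new_child(edge_length=eps)
            child.taxon = tns.new_taxon(label=entity)
    tree.update_taxon_namespace()
    return tree


def _design_from_factor(values: pd.Series) -> tuple[np.ndarray, list[str], list[str]]:
    levels = sorted(values.unique())
    if len(levels) < 2:
        raise ValueError(f"trait has a single level {levels}; no contrast to fit")
    X = np.column_stack(
        [np.ones(len(values))] + [(values == lv).astype(float) for lv in levels[1:]]
    )
    names = ["intercept"] + [str(lv) for lv in levels[1:]]
    return X, names, [str(lv) for lv in levels]


def _group_means(fit: PGLSFit, levels: list[str]) -> list[dict]:
    """Predicted mean +/- SE per factor level from the fitted contrasts."""
    out = []
    b = list(fit.coefficients.values())
    cov = fit.coef_cov
    for idx, level in enumerate(levels):
        if idx == 0:
            mean, var = b[0], cov[0, 0]
        else:
            mean = b[0] + b[idx]
            var = cov[0, 0] + cov[idx, idx] + 2.0 * cov[0, idx]
        out.append({"level": level, "mean": float(mean), "se": float(math.sqrt(max(var, 0.0)))})
    return out


def fit_all_models(
    y, X, tree, *, taxa, coef_names=None, kinds=MODEL_KINDS, reml: bool = True
) -> tuple[PGLSFit, list[PGLSFit]]:
    fits = []
    for kind in kinds:
        try:
            fits.append(
                pgls_fit(y, X, tree, kind, taxa=list(taxa), coef_names=coef_names, reml=reml)
            )
        except (ValueError, np.linalg.LinAlgError):
            continue
    return select_model(fits), fits


def trait_sensitivity_analysis(
    slopes: pd.DataFrame,
    traits: pd.DataFrame,
    tree: dendropy.Tree,
    *,
    population_trends: pd.DataFrame | None = None,
    traits_of_interest: tuple[str, ...] = ("lts", "ldc", "voltinism"),
    kinds=MODEL_KINDS,
) -> pd.DataFrame:
    """PGLS of every slope set on every trait, plus slope ~ population trend.

    ``slopes`` is tidy (taxon, response, predictor, slope); each distinct
    (response, predictor) pair is a response vector.  For each ecological
    trait the three covariance models are fitted and the AIC winner
    reported, with predicted group means +/- SE.  If ``population_trends``
    (taxon, trend) is given, the year-slopes are additionally regressed on
    the trend as a continuous predictor.
    """
    tr = traits.set_index("taxon")
    rows = []
    for (response, predictor), grp in slopes.groupby(["response", "predictor"]):
        grp = grp.dropna(subset=["slope"])
        taxa = list(grp["taxon"])
        y = grp["slope"].to_numpy(dtype=float)
        analyses: list[tuple[str, np.ndarray, list[str], list[str] | None]] = []
        for trait in traits_of_interest:
            vals = tr.loc[taxa, trait]
            X, names, levels = _design_from_factor(vals.reset_index(drop=True))
            analyses.append((trait, X, names, levels))
        if population_trends is not None and predictor == "year":
            pt = population_trends.set_index("taxon")["trend"]
            ok = [t in pt.index and pd.notna(pt[t]) for t in taxa]
            if sum(ok) > 3:
                sub_taxa = [t for t, k in zip(taxa, ok) if k]
                Xc = np.column_stack(
                    [np.ones(len(sub_taxa)), pt.loc[sub_taxa].to_numpy(dtype=float)]
                )
                analyses.append(
                    ("population_trend", (Xc, sub_taxa, y[np.asarray(ok)]), None, None)
                )
        for trait, X, names, levels in analyses:
            if trait == "population_trend":
                Xc, sub_taxa, y_sub = X
                best, _ = fit_all_models(
                    y_sub, Xc, tree, taxa=sub_taxa,
                    coef_names=["intercept", "population_trend"], kinds=kinds,
                )
                slope_coef = best.coefficients["population_trend"]
                rows.append(
                    {
                        "response": response, "predictor": predictor, "trait": trait,
                        "model": best.model.kind, "lambda": best.model.lam,
                        "alpha": best.model.alpha, "f_statistic": best.f_statistic,
                        "p_value": best.p_value, "aic": best.aic, "n": best.n,
                        "effect": slope_coef, "group_means": None,
                    }
                )
                continue
            best, _ = fit_all_models(y, X, tree, taxa=taxa, coef_names=names, kinds=kinds)
            means = _group_means(best, levels)
            effect = means[1]["mean"] - means[0]["mean"] if len(means) == 2 else float("nan")
            rows.append(
                {
                    "response": response, "predictor": predictor, "trait": trait,
                    "model": best.model.kind, "lambda": best.model.lam,
                    "alpha": best.model.alpha, "f_statistic": best.f_statistic,
                    "p_value": best.p_value, "aic": best.aic, "n": best.n,
                    "effect": effect,
                    "group_means": "; ".join(
                        f"{m['level']}: {m['mean']:.4g} +/- {m['se']:.4g}" for m in means
                    ),
                }
            )
    return pd.DataFrame(rows)
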