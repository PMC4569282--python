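"""Leatherback life-history parameters and the age-structured transition matrix.

The population model is a post-breeding-census Leslie–Lefkovitch matrix: it is
age-classified for ages 0..alpha-1 (alpha = age at first reproduction) plus a
single adult stage class with survival ``P_adult`` on the diagonal.  Because
the census is post-breeding, fertilities include the parent's survival over
the year, which lets eggs and hatchlings carry reproductive value and thereby
be managed as removals.

Parameter uncertainty is configured with :class:`LifeHistoryConfig`; one joint
draw is a :class:`LifeHistoryParams`.  Juvenile survival is not directly
observable for leatherbacks, so for each draw we solve the renewal
(characteristic) equation for the juvenile survivorship needed to reach the
drawn maximum growth rate ``lambda_m``, and spread it over ages with a
logarithmic-in-age curve (survival rises with size, and size rises
asymptotically with age).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .distributions import ConfigurationError, Dist

__all__ = [
    "LifeHistoryParams",
    "LifeHistoryConfig",
    "FertilityPair",
    "SurvivalCurve",
    "TransitionMatrix",
    "InfeasibleParameters",
    "sample_params",
    "derive_hatchling_survival",
    "compute_fertilities",
    "required_juvenile_survivorship",
    "solve_juvenile_survival",
    "assemble_matrix",
    "eigen_structure",
    "adult_equivalents",
    "build_transition_matrix",
]


class InfeasibleParameters(ValueError):
    """The target growth rate cannot be reached with survival in (0, 1]."""


@dataclass(frozen=True)
class LifeHistoryParams:
    """One joint realization (or the means) of the life-history parameters.

    Attributes
    ----------
    lambda_m : float
        Maximum (low-density) annual population growth multiplier.
    alpha : int
        Age at first reproduction (years).
    p_adult : float
        Annual adult survival probability.
    p_alpha : float
        Survival of the final sub-adult age class (taken equal to ``p_adult``).
    erosion : float
        Proportion of nests destroyed by beach erosion.
    emergence : float
        Proportion of eggs in an intact nest producing emerged hatchlings.
    first_day_survival : float
        Hatchling survival through the first day post-hatching.
    ri : float
        Remigration interval: years between successive nesting seasons.
    pf : float
        Proportion of females in the population.
    cf : float
        Clutch frequency (nests per nesting year).
    cs : float
        Clutch size (eggs per nest).
    f_neo : float
        Neophyte (first-time nester) fecundity relative to returning nesters.
    """

    lambda_m: float
    alpha: int
    p_adult: float
    p_alpha: float
    erosion: float
    emergence: float
    first_day_survival: float
    ri: float
    pf: float
    cf: float
    cs: float
    f_neo: float

    def __post_init__(self):
        for name in ("p_adult", "p_alpha", "erosion", "emergence",
                     "first_day_survival", "pf", "f_neo"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ConfigurationError(f"{name}={x} outside [0, 1]")
        if self.lambda_m < 1.0:
            raise ConfigurationError(f"lambda_m={self.lambda_m} must be >= 1")
        if self.alpha < 2:
            raise ConfigurationError(f"alpha={self.alpha} must be >= 2")
        if self.ri <= 1.0:
            raise ConfigurationError(f"ri={self.ri} must exceed 1")
        if self.cf <= 0 or self.cs <= 0:
            raise ConfigurationError("clutch frequency and size must be positive")


@dataclass(frozen=True)
class FertilityPair:
    """Annual egg production per adult and per neophyte-age individual."""

    f_adult: float
    f_alpha: float


@dataclass(frozen=True)
class SurvivalCurve:
    """Age-specific annual survival for classes 0..alpha.

    ``by_age[a]`` is the survival of age class ``a``; the last element is the
    adult stage survival.  ``geometric_mean_juvenile`` is the geometric mean
    over the solved classes 0..alpha-2 (age 0 includes the hatchling
    component).
    """

    by_age: np.ndarray
    geometric_mean_juvenile: float


@dataclass(frozen=True)
class TransitionMatrix:
    """A transition matrix with its dominant eigen-structure.

    ``w`` (stable age distribution) and ``v`` (reproductive values) are
    standardized so the adult (last) element equals 1; ``v`` is the common
    currency for adult-equivalent accounting.
    """

    entries: np.ndarray
    lam: float
    w: np.ndarray
    v: np.ndarray

    def to_frame(self):
        """The matrix as a labelled DataFrame (age classes 0..alpha-1, adult),
        convenient for CSV export and inspection."""
        import pandas as pd
        m = len(self.entries)
        labels = [f"age_{i}" for i in range(m - 1)] + ["adult"]
        return pd.DataFrame(self.entries, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# Parameter configuration and sampling
# ---------------------------------------------------------------------------

def _default_dists() -> dict[str, Dist]:
    return {
        "lambda_m": Dist.uniform(1.04, 1.06),
        "p_adult": Dist.uniform(0.88, 0.96),
        "erosion": Dist.beta(9.7, 20.2),
        "emergence": Dist.beta(2.8, 4.2),
        "pf": Dist.beta(27.5, 10.5),
    }


@dataclass(frozen=True)
class LifeHistoryConfig:
    """Distributional configuration for the life-history parameters.

    Defaults follow the literature-review values for boreal-summer-nesting
    western Pacific leatherbacks: lambda_m ~ U(1.04, 1.06), adult survival
    U(0.88, 0.96), erosion Beta(9.7, 20.2), emergence Beta(2.8, 4.2),
    proportion female Beta(27.5, 10.5); alpha = 13, RI = 2.5 yr, CF = 5.5
    nests/yr, CS = 78 eggs, neophyte factor 0.68 and first-day hatchling
    survival 0.55 are treated as fixed.
    """

    dists: dict[str, Dist] = field(default_factory=_default_dists)
    alpha: int = 13
    ri: float = 2.5
    cf: float = 5.5
    cs: float = 78.0
    f_neo: float = 0.68
    first_day_survival: float = 0.55

    def _build(self, value_of) -> LifeHistoryParams:
        p_adult = value_of("p_adult")
        return LifeHistoryParams(
            lambda_m=value_of("lambda_m"),
            alpha=self.alpha,
            p_adult=p_adult,
            p_alpha=p_adult,  # final sub-adult survival taken equal to adult
            erosion=value_of("erosion"),
            emergence=value_of("emergence"),
            first_day_survival=self.first_day_survival,
            ri=self.ri,
            pf=value_of("pf"),
            cf=self.cf,
            cs=self.cs,
            f_neo=self.f_neo,
        )

    def sample(self, rng: np.random.Generator) -> LifeHistoryParams:
        return self._build(lambda k: float(self.dists[k].sample(rng)))

    def means(self) -> LifeHistoryParams:
        return self._build(lambda k: self.dists[k].mean())


def sample_params(rng: np.random.Generator,
                  spec: LifeHistoryConfig | None = None) -> LifeHistoryParams:
    """Draw one independent joint realization of the life-history parameters."""
    spec = spec if spec is not None else LifeHistoryConfig()
    return spec.sample(rng)


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

def derive_hatchling_survival(params: LifeHistoryParams) -> float:
    """Survival through the first day post-hatching.

    The product emergence x (1 - erosion) x first-day survival; at the
    default parameter means this is ~0.149 (0.15 at two decimals).
    """
    return params.emergence * (1.0 - params.erosion) * params.first_day_survival


def compute_fertilities(params: LifeHistoryParams) -> FertilityPair:
    """Post-breeding-census fertilities (eggs per year).

    Adults: ``P_adult x PF x (1/RI) x CF x CS``.  Neophytes (first-time
    nesters entering the adult class) carry the extra fecundity factor
    ``f_neo`` and the final sub-adult survival.
    """
    base = params.pf * (1.0 / params.ri) * params.cf * params.cs
    return FertilityPair(
        f_adult=params.p_adult * base,
        f_alpha=params.p_alpha * base * params.f_neo,
    )


def required_juvenile_survivorship(params: LifeHistoryParams,
                                   fertilities: FertilityPair,
                                   target_lambda: float) -> float:
    """Juvenile survivorship product required to reach ``target_lambda``.

    The renewal equation for this matrix,

        1 = L [ F_alpha lam^-alpha + F_adult P_alpha lam^-(alpha+1) / (1 - P_adult/lam) ],

    is linear in the survivorship L = s_0 s_1 ... s_{alpha-2}, so the
    characteristic-equation root is available in closed form.  Requires
    ``target_lambda > p_adult`` (the adult self-loop is a hard floor on the
    attainable growth rate).
    """
    lam = float(target_lambda)
    if lam <= params.p_adult:
        raise InfeasibleParameters(
            f"target lambda {lam} not attainable: at juvenile survival -> 0 the "
            f"growth rate floor is the adult survival {params.p_adult}"
        )
    a = params.alpha
    denom = (fertilities.f_alpha * lam ** (-a)
             + fertilities.f_adult * params.p_alpha * lam ** (-(a + 1))
             / (1.0 - params.p_adult / lam))
    if denom <= 0:
        raise InfeasibleParameters("nonpositive fertility: no growth possible")
    L = 1.0 / denom
    if L > 1.0:
        raise InfeasibleParameters(
            f"target lambda {lam} requires juvenile survivorship {L:.4g} > 1 "
            f"for draw {params}"
        )
    return L


def _log_curve(c0: float, c1: float, ages: np.ndarray) -> np.ndarray:
    return c0 + c1 * np.log(ages + 1.0)


def solve_juvenile_survival(params: LifeHistoryParams,
                            fertilities: FertilityPair,
                            target_lambda: float,
                            slope_multiplier: float = 1.0) -> SurvivalCurve:
    """Solve for the age-specific juvenile survival curve at ``target_lambda``.

    Two-step procedure: (i) closed-form solve of the renewal equation for the
    total juvenile survivorship L over classes 0..alpha-2; (ii) distribute L
    over ages with a logarithmic curve ``j(a) = c0 + c1 ln(a+1)`` anchored so
    that it meets the adult survival at age alpha-1 (continuity) while the
    product constraint ``P_hatch j(0) j(1) ... j(alpha-2) = L`` holds exactly.
    Age-0 survival is the first-day hatchling survival times the curve's
    first-year component.

    ``slope_multiplier`` steepens (>1) or flattens (<1) the fitted curve while
    re-centring the intercept to preserve the survivorship product — used by
    the sensitivity trials; the default 1.0 keeps the continuity anchor.
    """
    a = params.alpha
    L = required_juvenile_survivorship(params, fertilities, target_lambda)
    p_hatch = derive_hatchling_survival(params)
    if p_hatch <= 0.0:
        raise InfeasibleParameters("hatchling survival is zero; no cohort can recruit")
    target_log_prod = np.log(L) - np.log(p_hatch)  # required sum of ln j(a)
    ages = np.arange(a - 1, dtype=float)  # juvenile classes 0..alpha-2

    def log_prod(c1: float) -> float:
        c0 = params.p_adult - c1 * np.log(a + 1.0)  # continuity: j(alpha-1)=P_adult
        j = _log_curve(c0, c1, ages)
        if np.any(j <= 0.0):
            return -np.inf
        return float(np.sum(np.log(j)))

    # The product is monotone decreasing in the slope (intercept anchored at
    # the adult end), so the slope solving the product constraint is unique.
    # Slope may go slightly negative (survival above the adult rate at young
    # ages) for draws with very low hatchling survival; j(0) <= 1 caps it.
    c1_max = params.p_adult / np.log(a + 1.0)
    c1_min = (params.p_adult - 1.0) / np.log(a + 1.0)
    if log_prod(c1_min) < target_log_prod:
        raise InfeasibleParameters(
            "required juvenile survivorship exceeds the ceiling with all "
            f"survival probabilities at 1 for draw {params}"
        )
    # log_prod -> -inf as c1 -> c1_max (j(0) -> 0), so the root is bracketed.
    lo, hi = c1_min, c1_max * (1.0 - 1e-9)
    c1 = brentq(lambda c: log_prod(c) - target_log_prod, lo, hi, xtol=1e-12)
    c0 = params.p_adult - c1 * np.log(a + 1.0)

    j = _log_curve(c0, c1, ages)
    if slope_multiplier != 1.0:
        # Steepen (>1) or flatten (<1) the rise of survival with age while
        # preserving the survivorship product exactly: a power transform about
        # the geometric mean in log space.  Continuity with the adult end is
        # dropped, as the product (hence the eigenvalue) is what must be kept.
        mean_log = float(np.mean(np.log(j)))
        j = np.exp(slope_multiplier * (np.log(j) - mean_log) + mean_log)
        if np.any(j > 1.0):
            raise InfeasibleParameters(
                f"slope multiplier {slope_multiplier} pushes a juvenile survival "
                "above 1 while preserving the survivorship product")
    by_age = np.empty(a + 1)
    by_age[0] = p_hatch * j[0]
    by_age[1:a - 1] = j[1:]
    by_age[a - 1] = params.p_alpha
    by_age[a] = params.p_adult
    gm = float(np.exp((np.log(p_hatch * j[0]) + np.sum(np.log(j[1:]))) / (a - 1)))
    return SurvivalCurve(by_age=by_age, geometric_mean_juvenile=gm)


# ---------------------------------------------------------------------------
# Matrix assembly and eigen-structure
# ---------------------------------------------------------------------------

def assemble_matrix(params: LifeHistoryParams,
                    fertilities: FertilityPair,
                    curve: SurvivalCurve) -> TransitionMatrix:
    """Assemble the (alpha+1) x (alpha+1) post-breeding-census matrix.

    Sub-diagonal holds age-class survival, the last diagonal element is the
    adult stage survival, and the first row holds the neophyte fertility
    (final sub-adult column) and adult fertility (adult column).
    """
    a = params.alpha
    if len(curve.by_age) != a + 1:
        raise ConfigurationError(
            f"survival curve length {len(curve.by_age)} != alpha+1 = {a + 1}")
    A = np.zeros((a + 1, a + 1))
    for i in range(a):
        A[i + 1, i] = curve.by_age[i]
    A[a, a] = params.p_adult
    A[0, a - 1] = fertilities.f_alpha
    A[0, a] = fertilities.f_adult
    lam, w, v = eigen_structure(A)
    return TransitionMatrix(entries=A, lam=lam, w=w, v=v)


def eigen_structure(matrix: np.ndarray | TransitionMatrix):
    """Dominant eigenvalue with right (w) and left (v) eigenvectors.

    Both vectors are rescaled so the adult (last) element equals 1.
    """
    A = matrix.entries if isinstance(matrix, TransitionMatrix) else np.asarray(matrix, float)
    vals, vecs = np.linalg.eig(A)
    k = int(np.argmax(vals.real))
    lam = float(vals[k].real)
    w = np.abs(vecs[:, k].real)
    lvals, lvecs = np.linalg.eig(A.T)
    kl = int(np.argmin(np.abs(lvals - vals[k])))
    v = np.abs(lvecs[:, kl].real)
    if w[-1] <= 1e-12 or v[-1] <= 1e-12:
        # repeated dominant eigenvalue (e.g. a diagonal matrix): take a
        # positive combination of the whole dominant eigenspace instead
        from scipy.linalg import null_space
        w = np.abs(null_space(A - lam * np.eye(len(A)))).sum(axis=1)
        v = np.abs(null_space(A.T - lam * np.eye(len(A)))).sum(axis=1)
        if w[-1] <= 0 or v[-1] <= 0:
            raise np.linalg.LinAlgError(
                f"degenerate dominant eigenvectors for matrix:\n{A}")
    return lam, w / w[-1], v / v[-1]


def adult_equivalents(stage_vector: np.ndarray, v: np.ndarray) -> float:
    """Adult-equivalent count of a stage-abundance vector.

    The dot product of per-class counts with adult-standardized reproductive
    values: the common currency that makes removals of different life stages
    comparable.
    """
    n = np.asarray(stage_vector, float)
    v = np.asarray(v, float)
    if n.shape != v.shape:
        raise ValueError(f"length mismatch: {n.shape} vs {v.shape}")
    return float(n @ v)


def build_transition_matrix(params: LifeHistoryParams,
                            target_lambda: float | None = None,
                            slope_multiplier: float = 1.0,
                            fertility_multiplier: float = 1.0,
                            check_tol: float = 1e-6) -> TransitionMatrix:
    """Fertilities -> juvenile-survival solve -> matrix, with a round-trip check.

    ``target_lambda`` defaults to the draw's own ``lambda_m``.
    ``fertility_multiplier`` scales both fertilities before the survival
    re-solve (the solved matrix still hits the target eigenvalue; used by the
    fertility-bias sensitivity trial).
    """
    lam = params.lambda_m if target_lambda is None else float(target_lambda)
    fert = compute_fertilities(params)
    if fertility_multiplier != 1.0:
        fert = FertilityPair(f_adult=fert.f_adult * fertility_multiplier,
                             f_alpha=fert.f_alpha * fertility_multiplier)
    curve = solve_juvenile_survival(params, fert, lam, slope_multiplier)
    tm = assemble_matrix(params, fert, curve)
    if abs(tm.lam - lam) > check_tol:
        raise InfeasibleParameters(
            f"round-trip eigenvalue {tm.lam} missed target {lam} beyond {check_tol}")
    return tm
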