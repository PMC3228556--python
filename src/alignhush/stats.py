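"""Per-query E-value calibration.

Local-alignment scores of a query against unrelated profiles follow an
extreme-value (Gumbel) distribution.  Each query is calibrated by aligning
it to a random profile database and fitting Gumbel location/scale (mu,
lambda) to the score sample by maximum likelihood; searches then report
E = N * P(score' >= score) with N the size of the searched database.
Calibration is per query rather than database-wide to avoid bias from
profile length and composition.

To guard against true homologs contaminating a randomly selected calibration
database, the top fraction of scores can be type-2 censored: the censored
observations contribute only their survival probability to the likelihood.
"""

from __future__ import annotations

import copy
import io
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import CalibrationError, SamplingError
from .hmm_io import AlignHushProfile
from .scoring import ScoringParams

EULER_GAMMA = 0.5772156649015329


@dataclass
class EvalueFit:
    """Gumbel parameters for one query plus the effective database size."""

    lam: float  # scale, 1/bits
    mu: float  # location, bits
    n_calibration: int
    db_size: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.lam > 0):
            raise ValueError("lambda must be positive")

    @property
    def reliable(self) -> bool:
        return self.n_calibration >= 50


def fit_gumbel(
    scores: np.ndarray, censor_frac: float = 0.0
) -> tuple[float, float]:
    """Maximum-likelihood Gumbel (lambda, mu) fit with moment initialisation.

    With ``censor_frac`` > 0 the largest ceil(frac*n) observations are
    type-2 censored at the largest retained order statistic: they enter the
    likelihood only through the survival term ``(1 - F(c))**n_cens``.
    """
    x = np.sort(np.asarray(scores, dtype=float))
    n = len(x)
    if n < 2:
        raise CalibrationError("need at least two scores to fit")
    sd = x.std()
    if sd == 0:
        raise CalibrationError("degenerate score sample (zero variance)")

    lam0 = math.pi / (sd * math.sqrt(6.0))
    mu0 = x.mean() - EULER_GAMMA / lam0

    n_cens = int(math.ceil(censor_frac * n)) if censor_frac > 0 else 0
    if n_cens >= n - 1:
        raise CalibrationError("censoring leaves too few observations")
    kept = x[: n - n_cens] if n_cens else x
    c = kept[-1]

    def nll(theta):
        loglam, mu = theta
        lam = math.exp(loglam)
        z = lam * (kept - mu)
        ll = len(kept) * loglam - z.sum() - np.exp(-z).sum()
        if n_cens:
            zc = lam * (c - mu)
            # survival 1 - exp(-exp(-zc)), numerically via expm1
            surv = -math.expm1(-math.exp(-zc))
            if surv <= 0:
                return np.inf
            ll += n_cens * math.log(surv)
        return -ll

    res = optimize.minimize(
        nll, x0=(math.log(lam0), mu0), method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    if not res.success:  # pragma: no cover - Nelder-Mead rarely fails here
        raise CalibrationError(f"Gumbel fit did not converge: {res.message}")
    return math.exp(res.x[0]), float(res.x[1])


def calibrate(
    query: AlignHushProfile,
    random_db: list[AlignHushProfile],
    params: ScoringParams | None = None,
    db_size: float | None = None,
    censor_frac: float = 0.01,
    seed: int | None = None,
) -> EvalueFit:
    """Fit per-query Gumbel parameters from alignments to a random database."""
    from .align import viterbi_align

    if len(random_db) < 50:
        raise CalibrationError(
            f"calibration database has {len(random_db)} profiles, need >= 50"
        )
    params = params or ScoringParams()
    scores = np.array(
        [viterbi_align(query, t, params).score for t in random_db]
    )
    lam, mu = fit_gumbel(scores, censor_frac=censor_frac)
    return EvalueFit(
        lam=lam,
        mu=mu,
        n_calibration=len(random_db),
        db_size=db_size if db_size is not None else len(random_db),
        seed=seed,
    )


def evalue(score: float, fit: EvalueFit) -> float:
    """Expected number of random profiles scoring at least this well.

    p = 1 - exp(-exp(-lambda (score - mu))); E = db_size * p, clamped to
    [0, db_size].
    """
    z = fit.lam * (score - fit.mu)
    # stable 1 - exp(-exp(-z))
    p = -math.expm1(-math.exp(-z)) if z > -30 else 1.0
    return min(max(fit.db_size * p, 0.0), fit.db_size)


def make_random_db(
    profile_pool: list[AlignHushProfile],
    size: int,
    seed: int,
    shuffle: bool = False,
) -> list[AlignHushProfile]:
    """Draw a seeded random calibration database from a profile pool.

    Without shuffling, profiles are sampled without replacement (so ``size``
    cannot exceed the pool).  In shuffle mode each sampled profile's match
    states are randomly permuted, destroying residual homology; sampling is
    then allowed to exceed the pool (with replacement).
    """
    if not profile_pool:
        raise SamplingError("empty profile pool")
    rng = np.random.default_rng(seed)
    npool = len(profile_pool)
    if size > npool and not shuffle:
        raise SamplingError(
            f"requested {size} profiles from a pool of {npool} "
            "without replacement; enable shuffle mode to oversample"
        )
    idx = rng.choice(npool, size=size, replace=size > npool)
    out = []
    for k, i in enumerate(idx):
        prof = profile_pool[int(i)]
        if shuffle:
            perm = rng.permutation(len(prof))
            shuffled = copy.deepcopy(prof)
            shuffled.states = [prof.states[p] for p in perm]
            shuffled.name = f"{prof.name}|shuf{k}"
            shuffled._cache = {}
            out.append(shuffled)
        else:
            out.append(prof)
    return out


# ---------------------------------------------------------------------------
# sidecar serialisation


def write_fit(fit: EvalueFit, stream) -> None:
    stream.write("ALIGNHUSH-EVD 1\n")
    stream.write(f"lambda {fit.lam:.9e}\n")
    stream.write(f"mu {fit.mu:.9e}\n")
    stream.write(f"n {fit.n_calibration}\n")
    stream.write(f"db_size {fit.db_size:.9e}\n")
    if fit.seed is not None:
        stream.write(f"seed {fit.seed}\n")


def read_fit(stream) -> EvalueFit:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = [ln.split() for ln in stream if ln.strip()]
    if not lines or lines[0][0] != "ALIGNHUSH-EVD":
        raise CalibrationError("not an E-value calibration sidecar")
    kv = {toks[0]: toks[1] for toks in lines[1:]}
    return EvalueFit(
        lam=float(kv["lambda"]),
        mu=float(kv["mu"]),
        n_calibration=int(kv["n"]),
        db_size=float(kv["db_size"]),
        seed=int(kv["seed"]) if "seed" in kv else None,
    )
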