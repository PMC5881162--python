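"""Virtual-population efavirenz pharmacokinetics.

A reduced population-PK surrogate for the whole-body PBPK engine used to
generate the original virtual cohorts: disposition is a one-compartment model
with first-order absorption,

    C(t) = F·D·ka / (V·(ka − k)) · (exp(−k·t) − exp(−ka·t)),   k = CL/V,

with between-subject variability carried by independent lognormal
distributions on CL/F, V/F and ka. Phenotype enters only through the
clearance distribution (and, via calibration, the volume): EM, IM and PM
populations are calibrated so that the population mean AUC(0−∞), Cmax and
CL/F reproduce the published predicted summary statistics for each phenotype
after a single 600 mg oral dose. Only the marginal concentration
distributions at the sampling times feed the downstream Bayesian classifier,
so the surrogate is judged on those marginals, not on mechanistic fidelity.

Units: dose mg, CL L/h, V L, ka 1/h, time h, concentration ng/mL,
AUC µg·h/mL (≡ mg·h/L).
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import brentq

from .dataset import CohortDataset
from .phenotype import PHENOTYPES, Phenotype, coerce_phenotype

#: Published predicted population PK summary per phenotype, single 600 mg dose
#: (means: CL/F L/h, AUC(0−∞) µg·h/mL, Cmax ng/mL). These are the default
#: calibration targets of the virtual population.
PREDICTED_PK = {
    Phenotype.EM: {"mean_cl": 12.8, "mean_auc": 66.8, "mean_cmax": 1850.0},
    Phenotype.IM: {"mean_cl": 6.9, "mean_auc": 108.4, "mean_cmax": 1952.0},
    Phenotype.PM: {"mean_cl": 4.7, "mean_auc": 153.2, "mean_cmax": 2135.0},
}

#: Published observed reference means (same layout) used only for
#: predicted:observed ratio reporting, never for calibration.
OBSERVED_PK = {
    Phenotype.EM: {"mean_cl": 7.57, "mean_auc": 68.0, "mean_cmax": 1642.0},
    Phenotype.IM: {"mean_cl": 7.14, "mean_auc": 77.0, "mean_cmax": 1878.0},
    Phenotype.PM: {"mean_cl": 4.09, "mean_auc": 123.0, "mean_cmax": 2344.0},
}

DEFAULT_DOSE_MG = 600.0
#: Classifier sampling times (h post-dose).
SAMPLING_TIMES = (2.0, 4.0, 8.0, 12.0, 24.0)
#: Dense grid for non-compartmental summaries: 0–72 h at 0.5 h.
DENSE_GRID = tuple(np.arange(0.0, 72.0 + 1e-9, 0.5))

_FLIPFLOP_TOL = 1e-6


class CalibrationError(RuntimeError):
    """No population spec satisfies the moment conditions."""


@dataclass(frozen=True)
class PhenotypePopulationSpec:
    """Lognormal between-subject distribution of individual PK parameters."""

    phenotype: Phenotype
    mean_cl: float  # L/h
    cv_cl: float
    mean_v: float  # L
    cv_v: float
    mean_ka: float  # 1/h
    cv_ka: float

    def __post_init__(self) -> None:
        for name in ("mean_cl", "mean_v", "mean_ka"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("cv_cl", "cv_v", "cv_ka"):
            cv = getattr(self, name)
            if not 0.0 <= cv <= 2.0:
                raise ValueError(f"{name}={cv} outside [0, 2]")


@dataclass(frozen=True)
class IndividualPKParameters:
    subject_id: str
    phenotype: Phenotype
    cl: float
    v: float
    ka: float

    def __post_init__(self) -> None:
        if min(self.cl, self.v, self.ka) <= 0:
            raise ValueError("cl, v, ka must be strictly positive")


# ----------------------------------------------------------------------
# lognormal helpers


def _lognormal_mu_sigma(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = np.log1p(cv * cv)
    return np.log(mean) - 0.5 * sigma2, np.sqrt(sigma2)


def _draw_lognormal(rng: np.random.Generator, mean, cv, size=None):
    if np.all(np.asarray(cv) == 0):
        return np.full(size, mean) if size is not None else mean
    mu, sigma = _lognormal_mu_sigma(mean, cv)
    return rng.lognormal(mu, sigma, size)


# ----------------------------------------------------------------------
# single-profile model


def simulate_concentration(params, dose: float, time) -> np.ndarray | float:
    """Plasma concentration (ng/mL) at ``time`` h after an oral ``dose`` mg.

    ``params`` is an :class:`IndividualPKParameters` or any object with
    ``cl``, ``v``, ``ka`` attributes. Vectorized over ``time``.
    """
    cl, v, ka = params.cl, params.v, params.ka
    return _concentration(cl, v, ka, dose, time)


def _concentration(cl, v, ka, dose, time):
    t = np.asarray(time, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    k = np.asarray(cl, dtype=float) / np.asarray(v, dtype=float)
    ka = np.asarray(ka, dtype=float)
    if np.any(np.abs(ka - k) < _FLIPFLOP_TOL):
        raise ValueError(
            "absorption and elimination rate constants coincide (flip-flop "
            "degeneracy); resample the individual"
        )
    # mg/L == µg/mL; scale ×1000 to ng/mL
    c = 1000.0 * dose * ka / (np.asarray(v, float) * (ka - k)) * (
        np.exp(-k * t) - np.exp(-ka * t)
    )
    c = np.maximum(c, 0.0)  # clip −0.0 / rounding at t=0
    return c if c.shape else float(c)


def _peak_concentration(cl, v, ka, dose):
    """Closed-form Cmax: tmax = ln(ka/k)/(ka − k)."""
    k = cl / v
    tmax = np.log(ka / k) / (ka - k)
    return 1000.0 * dose * ka / (v * (ka - k)) * (np.exp(-k * tmax) - np.exp(-ka * tmax))


# ----------------------------------------------------------------------
# calibration


def population_mean_cmax(spec: PhenotypePopulationSpec, dose: float, n_nodes: int = 24) -> float:
    """Deterministic population-mean Cmax by Gauss–Hermite quadrature over the
    three independent lognormal parameter distributions."""
    nodes, weights = hermegauss(n_nodes)
    weights = weights / weights.sum()

    def axis(mean, cv):
        if cv == 0:
            return np.array([mean]), np.array([1.0])
        mu, sigma = _lognormal_mu_sigma(mean, cv)
        return np.exp(mu + sigma * nodes), weights

    cl, w_cl = axis(spec.mean_cl, spec.cv_cl)
    v, w_v = axis(spec.mean_v, spec.cv_v)
    ka, w_ka = axis(spec.mean_ka, spec.cv_ka)
    CL, V, KA = np.meshgrid(cl, v, ka, indexing="ij")
    W = w_cl[:, None, None] * w_v[None, :, None] * w_ka[None, None, :]
    return float(np.sum(W * _peak_concentration(CL, V, KA, dose)))


def calibrate_clearance_cv(mean_cl: float, mean_auc: float, dose: float) -> float:
    """Between-subject CV of clearance from the lognormal moment identity.

    With CL lognormal, E[AUC] = dose·E[1/CL] = dose·(1 + CV²)/E[CL]; solving
    for CV reconciles a printed mean AUC with a printed mean CL that do not
    satisfy mean_auc = dose/mean_cl.
    """
    ratio = mean_auc * mean_cl / dose
    if ratio < 1.0:
        raise CalibrationError(
            f"infeasible targets: mean_auc·mean_cl/dose = {ratio:.4f} < 1; "
            "no lognormal clearance distribution has these moments"
        )
    return float(np.sqrt(ratio - 1.0))


def calibrate_population(
    targets: Mapping[Phenotype, Mapping[str, float]] | None = None,
    dose: float = DEFAULT_DOSE_MG,
    *,
    cv_v: float = 0.25,
    cv_ka: float = 0.30,
    mean_ka: float = 0.6,
    v_bounds: tuple[float, float] = (50.0, 1500.0),
    v_tol: float = 1e-3,
) -> dict[Phenotype, PhenotypePopulationSpec]:
    """Calibrate per-phenotype population specs to summary-statistic targets.

    For each phenotype: ``cv_cl`` solves the AUC/CL moment identity, and the
    mean volume of distribution is adjusted by bounded root finding so the
    quadrature population-mean Cmax matches ``mean_cmax``. Absorption is held
    at ``mean_ka`` (default 0.6 /h, a typical oral value) since Cmax alone
    cannot identify both V and ka.
    """
    targets = targets or PREDICTED_PK
    specs: dict[Phenotype, PhenotypePopulationSpec] = {}
    for ph in PHENOTYPES:
        if ph not in targets:
            continue
        tgt = targets[ph]
        try:
            cv_cl = calibrate_clearance_cv(tgt["mean_cl"], tgt["mean_auc"], dose)
        except CalibrationError as exc:
            raise CalibrationError(f"{ph.value}: {exc}") from None
        base = PhenotypePopulationSpec(
            phenotype=ph,
            mean_cl=tgt["mean_cl"],
            cv_cl=cv_cl,
            mean_v=250.0,
            cv_v=cv_v,
            mean_ka=mean_ka,
            cv_ka=cv_ka,
        )

        def resid(mean_v: float) -> float:
            return population_mean_cmax(replace(base, mean_v=mean_v), dose) - tgt["mean_cmax"]

        lo, hi = v_bounds
        r_lo, r_hi = resid(lo), resid(hi)
        if r_lo * r_hi > 0:
            raise CalibrationError(
                f"{ph.value}: Cmax target {tgt['mean_cmax']} ng/mL not bracketed "
                f"by mean_v in {v_bounds}; residuals ({r_lo:.1f}, {r_hi:.1f})"
            )
        mean_v = brentq(resid, lo, hi, xtol=v_tol, maxiter=200)
        specs[ph] = replace(base, mean_v=float(mean_v))
    if not specs:
        raise CalibrationError("no phenotype targets supplied")
    return specs


# ----------------------------------------------------------------------
# sampling and cohort simulation


def sample_individual(
    spec: PhenotypePopulationSpec,
    rng: np.random.Generator,
    subject_id: str = "s0",
    max_redraws: int = 100,
) -> IndividualPKParameters:
    """Draw one virtual subject; redraws on flip-flop degeneracy (cl/v ≈ ka)."""
    for _ in range(max_redraws):
        cl = float(_draw_lognormal(rng, spec.mean_cl, spec.cv_cl))
        v = float(_draw_lognormal(rng, spec.mean_v, spec.cv_v))
        ka = float(_draw_lognormal(rng, spec.mean_ka, spec.cv_ka))
        if abs(cl / v - ka) >= _FLIPFLOP_TOL:
            return IndividualPKParameters(subject_id, spec.phenotype, cl, v, ka)
    raise RuntimeError("could not sample away from flip-flop degeneracy")


def _trial_rng(seed: int, phenotype_key: int, trial: int) -> np.random.Generator:
    # independent child stream per (cohort flavour, trial): trial counts can
    # grow without reshuffling earlier trials
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(phenotype_key, trial)))


def simulate_cohort(
    specs: Mapping[Phenotype, PhenotypePopulationSpec] | PhenotypePopulationSpec,
    dose: float = DEFAULT_DOSE_MG,
    times: Sequence[float] = SAMPLING_TIMES,
    n_trials: int = 10,
    n_per_trial: int = 500,
    phenotype_mix: Mapping[Phenotype, float] | Phenotype | None = None,
    seed: int = 0,
    id_prefix: str = "",
    female_fraction: float = 0.5,
    stream_offset: int = 0,
) -> CohortDataset:
    """Simulate ``n_trials × n_per_trial`` virtual subjects at ``times``.

    ``phenotype_mix`` is a single phenotype, or a mapping of (possibly
    unnormalized) phenotype weights; omitted, it defaults to the single
    phenotype of ``specs`` when one spec is given, or equal weights. Sex is
    drawn (``female_fraction``) as metadata only: the model is sex-agnostic.
    """
    if isinstance(specs, PhenotypePopulationSpec):
        specs = {specs.phenotype: specs}
    times = np.asarray(sorted(times), dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")

    if phenotype_mix is None:
        if len(specs) == 1:
            phenotype_mix = next(iter(specs))
        else:
            phenotype_mix = {ph: 1.0 for ph in specs}
    if isinstance(phenotype_mix, (Phenotype, str)):
        phenotype_mix = {coerce_phenotype(phenotype_mix): 1.0}
    mix = {coerce_phenotype(ph): float(w) for ph, w in phenotype_mix.items() if w > 0}
    if not mix:
        raise ValueError("phenotype mix is empty")
    missing = [ph.value for ph in mix if ph not in specs]
    if missing:
        raise ValueError(f"no population spec for phenotype(s) {missing}")
    mix_ph = [ph for ph in PHENOTYPES if ph in mix]
    mix_p = np.array([mix[ph] for ph in mix_ph])
    mix_p = mix_p / mix_p.sum()

    key = stream_offset + (
        PHENOTYPES.index(mix_ph[0]) if len(mix_ph) == 1 else len(PHENOTYPES)
    )
    frames = []
    for trial in range(1, n_trials + 1):
        rng = _trial_rng(seed, key, trial)
        assign = rng.choice(len(mix_ph), size=n_per_trial, p=mix_p)
        female = rng.random(n_per_trial) < female_fraction  # metadata only
        cl = np.empty(n_per_trial)
        v = np.empty(n_per_trial)
        ka = np.empty(n_per_trial)
        for j, ph in enumerate(mix_ph):
            idx = np.flatnonzero(assign == j)
            if idx.size == 0:
                continue
            sp = specs[ph]
            cl[idx] = _draw_lognormal(rng, sp.mean_cl, sp.cv_cl, idx.size)
            v[idx] = _draw_lognormal(rng, sp.mean_v, sp.cv_v, idx.size)
            ka[idx] = _draw_lognormal(rng, sp.mean_ka, sp.cv_ka, idx.size)
        # resample flip-flop degenerate subjects one by one
        bad = np.flatnonzero(np.abs(cl / v - ka) < _FLIPFLOP_TOL)
        for i in bad:
            p = sample_individual(specs[mix_ph[assign[i]]], rng)
            cl[i], v[i], ka[i] = p.cl, p.v, p.ka

        conc = _concentration(cl[:, None], v[:, None], ka[:, None], dose, times[None, :])
        sids = [f"{id_prefix}t{trial:02d}s{i:04d}" for i in range(1, n_per_trial + 1)]
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": np.repeat(sids, times.size),
                    "phenotype": np.repeat([mix_ph[a].value for a in assign], times.size),
                    "time_h": np.tile(times, n_per_trial),
                    "conc_ng_ml": conc.ravel(),
                    "trial": trial,
                    "female": np.repeat(female, times.size),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df["phenotype"] = df["phenotype"].astype("string")
    return CohortDataset(df=df, dose=dose, design=(n_trials, n_per_trial), seed=seed)


# ----------------------------------------------------------------------
# non-compartmental summary


@dataclass(frozen=True)
class PKSummary:
    """Per-phenotype population summary mirroring the published layout:
    mean and 2.5–97.5 percentile interval of per-trial means, with
    predicted:observed ratios when a reference is supplied."""

    phenotype: Phenotype
    auc_inf: tuple[float, float, float]  # mean, lo, hi — µg·h/mL
    cmax: tuple[float, float, float]  # ng/mL
    cl: tuple[float, float, float]  # L/h
    ratio_pred_obs: dict[str, float] | None = None

    def acceptable(self, low: float = 0.5, high: float = 2.0) -> bool:
        """Two-fold prediction-error criterion on every available ratio."""
        if not self.ratio_pred_obs:
            return True
        return all(low <= r <= high for r in self.ratio_pred_obs.values())


def _auc_inf_per_subject(times: np.ndarray, conc: np.ndarray, n_terminal: int = 8):
    """Trapezoidal AUC(0−t_last) plus log-linear terminal extrapolation
    C_last/λz, per subject (rows of ``conc``). Returns (auc µg·h/mL, λz /h)."""
    auc_t = np.trapezoid(conc, times, axis=1)
    tail_t = times[-n_terminal:]
    tail_c = np.clip(conc[:, -n_terminal:], 1e-12, None)
    # slope of log C over the terminal window
    x = tail_t - tail_t.mean()
    lam = -(np.log(tail_c) @ x) / (x @ x)
    lam = np.maximum(lam, 1e-9)
    auc = (auc_t + conc[:, -1] / lam) / 1000.0  # ng/mL·h → µg·h/mL
    return auc, lam


def summarize_pk(
    dataset: CohortDataset,
    observed: Mapping[Phenotype, Mapping[str, float]] | None = None,
) -> dict[Phenotype, PKSummary]:
    """Non-compartmental population summary per phenotype.

    Requires a dense grid spanning at least 0–72 h (the study duration) and a
    design with ≥ 2 trials so the percentile interval of trial means exists.
    """
    times = dataset.times
    if times[0] > 0 or times[-1] < 72.0 - 1e-9:
        raise ValueError("summary grid must span 0–72 h")
    if dataset.df["trial"].nunique() < 2:
        raise ValueError("at least 2 trials required for interval estimation")
    if dataset.df["phenotype"].isna().any():
        raise ValueError("summarize_pk requires labelled records")

    out: dict[Phenotype, PKSummary] = {}
    for ph_token, sub in dataset.df.groupby("phenotype", sort=True):
        ph = coerce_phenotype(ph_token)
        wide = sub.pivot(index="subject_id", columns="time_h", values="conc_ng_ml")
        wide = wide.reindex(columns=times)
        conc = wide.to_numpy(float)
        auc, _ = _auc_inf_per_subject(times, conc)
        cmax = conc.max(axis=1)
        cl = dataset.dose / auc
        trial = sub.groupby("subject_id", sort=True)["trial"].first().reindex(wide.index)
        per_trial = pd.DataFrame(
            {"auc": auc, "cmax": cmax, "cl": cl, "trial": trial.to_numpy()}
        ).groupby("trial").mean()

        def stat(name, values):
            lo, hi = np.percentile(per_trial[name], [2.5, 97.5])
            return float(values.mean()), float(lo), float(hi)

        ratios = None
        if observed and ph in observed:
            obs = observed[ph]
            ratios = {
                "auc": float(auc.mean() / obs["mean_auc"]),
                "cmax": float(cmax.mean() / obs["mean_cmax"]),
                "cl": float(cl.mean() / obs["mean_cl"]),
            }
        out[ph] = PKSummary(
            phenotype=ph,
            auc_inf=stat("auc", auc),
            cmax=stat("cmax", cmax),
            cl=stat("cl", cl),
            ratio_pred_obs=ratios,
        )
    return out


def summary_table(summaries: Mapping[Phenotype, PKSummary]) -> pd.DataFrame:
    """Long-format table mirroring the published parameter summary."""
    rows = []
    for ph in PHENOTYPES:
        if ph not in summaries:
            continue
        s = summaries[ph]
        for name, (mean, lo, hi), key in (
            ("AUC(0-inf) ug.h/mL", s.auc_inf, "auc"),
            ("Cmax ng/mL", s.cmax, "cmax"),
            ("CL L/h", s.cl, "cl"),
        ):
            rows.append(
                {
                    "phenotype": ph.value,
                    "parameter": name,
                    "predicted_mean": mean,
                    "ci_low": lo,
                    "ci_high": hi,
                    "ratio_pred_obs": (s.ratio_pred_obs or {}).get(key, np.nan),
                }
            )
    return pd.DataFrame(rows)
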