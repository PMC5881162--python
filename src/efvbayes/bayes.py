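"""Empirical-Bayes phenotype classification from one binned concentration.

The trained model is, per sampling time, the empirical conditional
distribution of the rounded concentration given phenotype,

    P(C | e_j) = #{subjects of phenotype e_j whose rounded concentration is C}
                 / #{subjects of phenotype e_j},

over bins of width 100 ng/mL (concentrations rounded to the nearest 100,
half-up). Bayes' rule with priors P(e_j) gives the posterior

    P(e_j | C) = P(e_j) P(C | e_j) / Σ_k P(e_k) P(C | e_k),

and the maximum-a-posteriori phenotype is the call. Priors default to
uniform (each phenotype equally represented in training). Laplace-style
smoothing (default pseudo-count 0.5 over the populated bin range plus guard
bins) keeps the posterior defined for unseen concentrations; with smoothing
disabled the conditional table is the exact count ratio and an all-zero
likelihood falls back to the nearest populated bin.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .dataset import CohortDataset
from .phenotype import PHENOTYPES, TIE_ORDER, Phenotype, coerce_phenotype

_TIE_RTOL = 1e-12


def bin_concentration(concentration: float, bin_width: float = 100.0) -> float:
    """Round a concentration to the nearest multiple of ``bin_width``.

    Exact midpoints round up (half-up), so 1250 → 1300 at width 100.
    """
    if concentration < 0:
        raise ValueError(f"negative concentration {concentration}")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    return math.floor(concentration / bin_width + 0.5) * bin_width


@dataclass
class BinnedConditionalTable:
    """Empirical P(concentration bin | phenotype) at one sampling time."""

    sampling_time: float
    bin_width: float
    bin_centers: np.ndarray  # ascending multiples of bin_width
    counts: dict[Phenotype, np.ndarray]  # raw training counts per bin
    priors: dict[Phenotype, float]
    smoothing: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        total_prior = sum(self.priors.values())
        if total_prior <= 0:
            raise ValueError("priors must have positive total mass")
        self.priors = {ph: p / total_prior for ph, p in self.priors.items()}

    @property
    def n_train(self) -> dict[Phenotype, int]:
        return {ph: int(c.sum()) for ph, c in self.counts.items()}

    def probabilities(self, phenotype: Phenotype) -> np.ndarray:
        """Smoothed conditional probabilities over ``bin_centers`` (sum to 1)."""
        c = self.counts[phenotype]
        return (c + self.smoothing) / (c.sum() + self.smoothing * c.size)

    def _bin_index(self, concentration: float) -> int:
        """Bin index for a concentration; out-of-range values clamp to the
        guard bins at either end."""
        center = bin_concentration(concentration, self.bin_width)
        idx = int(round((center - self.bin_centers[0]) / self.bin_width))
        return min(max(idx, 0), self.bin_centers.size - 1)

    def likelihoods(self, concentration: float) -> dict[Phenotype, float]:
        i = self._bin_index(concentration)
        lik = {ph: float(self.probabilities(ph)[i]) for ph in self.counts}
        if all(v == 0.0 for v in lik.values()):
            # unsmoothed model queried at an empty bin: nearest populated bin,
            # distance in bins, ties toward the higher concentration
            occupied = np.flatnonzero(sum(self.counts.values()) > 0)
            j = occupied[np.argmin(np.abs(occupied - i) - 1e-9 * occupied)]
            lik = {ph: float(self.probabilities(ph)[j]) for ph in self.counts}
        return lik

    # -- serialization -------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "sampling_time_h": self.sampling_time,
            "bin_width": self.bin_width,
            "priors": {ph.value: self.priors[ph] for ph in self.counts},
            "smoothing": self.smoothing,
            "tables": {
                ph.value: {
                    f"{c:g}": p
                    for c, p in zip(self.bin_centers, self.probabilities(ph))
                }
                for ph in self.counts
            },
            "counts": {
                ph.value: {
                    f"{c:g}": int(n)
                    for c, n in zip(self.bin_centers, self.counts[ph])
                }
                for ph in self.counts
            },
            "provenance": {**self.provenance, "n_train": {ph.value: n for ph, n in self.n_train.items()}},
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "BinnedConditionalTable":
        text = Path(source).read_text(encoding="utf-8") if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        some = next(iter(payload["counts"].values()))
        centers = np.array(sorted(float(c) for c in some), dtype=float)
        counts = {
            coerce_phenotype(ph): np.array(
                [tab[f"{c:g}"] for c in centers], dtype=float
            )
            for ph, tab in payload["counts"].items()
        }
        return cls(
            sampling_time=payload["sampling_time_h"],
            bin_width=payload["bin_width"],
            bin_centers=centers,
            counts=counts,
            priors={coerce_phenotype(ph): p for ph, p in payload["priors"].items()},
            smoothing=payload["smoothing"],
            provenance=payload.get("provenance", {}),
        )


@dataclass(frozen=True)
class PosteriorCurve:
    """P(phenotype | concentration bin) across bins at one sampling time."""

    sampling_time: float
    bin_centers: np.ndarray
    posteriors: dict[Phenotype, np.ndarray]
    populated: np.ndarray  # bool, any training count in the bin


@dataclass(frozen=True)
class PhenotypeCall:
    subject_id: str
    predicted: Phenotype
    posterior: dict[Phenotype, float]
    tie_flag: bool


# ----------------------------------------------------------------------


def fit_conditional_table(
    training: CohortDataset,
    sampling_time: float,
    bin_width: float = 100.0,
    priors: Mapping[Phenotype, float] | None = None,
    smoothing: float = 0.5,
    guard_bins: int = 2,
) -> BinnedConditionalTable:
    """Fit the empirical conditional table at one sampling time.

    The bin range is the contiguous span of populated bins extended by
    ``guard_bins`` on each side (never below zero); smoothing spreads its
    pseudo-count over that whole range.
    """
    records = training.at_time(sampling_time)
    if records["phenotype"].isna().any():
        raise ValueError("training records must all carry a phenotype label")
    conc = records["conc_ng_ml"].to_numpy(float)
    centers_per_record = np.array([bin_concentration(c, bin_width) for c in conc])
    labels = records["phenotype"].map(lambda p: coerce_phenotype(p)).to_numpy()

    present = set(labels)
    missing = [ph.value for ph in PHENOTYPES if ph not in present]
    if missing:
        raise ValueError(
            f"phenotype(s) {missing} have no training records at {sampling_time} h"
        )

    lo = max(centers_per_record.min() - guard_bins * bin_width, 0.0)
    hi = centers_per_record.max() + guard_bins * bin_width
    bin_centers = np.arange(lo, hi + bin_width / 2, bin_width)
    counts = {}
    for ph in PHENOTYPES:
        sel = centers_per_record[labels == ph]
        idx = np.round((sel - lo) / bin_width).astype(int)
        counts[ph] = np.bincount(idx, minlength=bin_centers.size).astype(float)
    if priors is None:
        priors = {ph: 1.0 / len(PHENOTYPES) for ph in PHENOTYPES}
    return BinnedConditionalTable(
        sampling_time=float(sampling_time),
        bin_width=float(bin_width),
        bin_centers=bin_centers,
        counts=counts,
        priors=dict(priors),
        smoothing=float(smoothing),
        provenance={"seed": training.seed, "design": list(training.design)},
    )


def posterior_probability(
    table: BinnedConditionalTable, concentration: float
) -> dict[Phenotype, float]:
    """Posterior P(phenotype | concentration) by Bayes' rule."""
    if concentration < 0:
        raise ValueError(f"negative concentration {concentration}")
    lik = table.likelihoods(concentration)
    weighted = {ph: table.priors.get(ph, 0.0) * l for ph, l in lik.items()}
    z = sum(weighted.values())
    if z == 0.0:
        # only reachable when priors zero out every positive-likelihood class
        support = [ph for ph in TIE_ORDER if table.priors.get(ph, 0.0) > 0]
        return {ph: (1.0 if ph is support[0] else 0.0) for ph in lik}
    return {ph: w / z for ph, w in weighted.items()}


def _argmax_phenotype(posterior: Mapping[Phenotype, float]) -> tuple[Phenotype, bool]:
    best = max(posterior.values())
    tied = [
        ph
        for ph in TIE_ORDER
        if ph in posterior and math.isclose(posterior[ph], best, rel_tol=_TIE_RTOL)
    ]
    return tied[0], len(tied) > 1


def classify(
    table: BinnedConditionalTable, concentration: float, subject_id: str = ""
) -> PhenotypeCall:
    """MAP phenotype call; ties break toward the slower metabolizer
    (PM over IM over EM) with ``tie_flag`` set."""
    post = posterior_probability(table, concentration)
    predicted, tie = _argmax_phenotype(post)
    return PhenotypeCall(subject_id, predicted, post, tie)


def posterior_curve(table: BinnedConditionalTable) -> PosteriorCurve:
    """Posterior of each phenotype across all bins of the table."""
    posts = {ph: np.empty(table.bin_centers.size) for ph in table.counts}
    for i, c in enumerate(table.bin_centers):
        p = posterior_probability(table, c)
        for ph in posts:
            posts[ph][i] = p[ph]
    populated = sum(table.counts.values()) > 0
    return PosteriorCurve(table.sampling_time, table.bin_centers.copy(), posts, populated)


def phenotype_concentration_ranges(
    curve: PosteriorCurve,
) -> dict[Phenotype, list[tuple[float, float]]]:
    """Concentration intervals (bin-center spans) where each phenotype is the
    MAP call; together the intervals partition the bin range."""
    if curve.bin_centers.size == 0:
        raise ValueError("empty posterior curve")
    calls = []
    for i in range(curve.bin_centers.size):
        ph, _ = _argmax_phenotype({p: curve.posteriors[p][i] for p in curve.posteriors})
        calls.append(ph)
    out: dict[Phenotype, list[tuple[float, float]]] = {ph: [] for ph in curve.posteriors}
    start = 0
    for i in range(1, len(calls) + 1):
        if i == len(calls) or calls[i] is not calls[start]:
            out[calls[start]].append(
                (float(curve.bin_centers[start]), float(curve.bin_centers[i - 1]))
            )
            start = i
    return out
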