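"""Seeded synthetic-data generators.

Two generators make every pipeline stage testable without field data:

* geochemical *scenarios* — log-normal perturbations of a base site's
  concentrations (multiplicative, reflecting the roughly log-scale
  variability of repeat spring measurements) with additive Gaussian
  jitter on pH and temperature;
* *Grd sequences* — proteins that carry the GrdB or GrdF conserved
  motif by construction (random wildcard/gap/alternative instantiation,
  random flanks), plus residue-frequency-matched decoys obtained by
  shuffling positives, with truth labels in a sidecar TSV.

All randomness flows through one :class:`numpy.random.Generator`
(PCG64) constructed from the integer seed, so identical specs give
identical output on every platform.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .conditions import SiteConditions
from .errors import ConfigError
from .motifs import (AMINO_ACIDS, AnyOf, Gap, Literal, MotifPattern,
                     GRDB_MOTIF, GRDF_MOTIF, match_motif)

__all__ = [
    "ScenarioSpec", "SyntheticSeqSpec", "generate_scenarios",
    "generate_grd_sequences", "instantiate_motif", "write_fasta",
    "write_labels",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Log-normal perturbation plan around a base site.

    ``sigma_conc`` is the natural-log standard deviation applied
    multiplicatively to every concentration (per-species overrides via
    ``sigma_by_species``); pH and temperature get additive Gaussian
    noise.  Defaults emulate repeat-sampling variability of spring
    geochemistry: a ~30% concentration spread, 0.1 pH unit, 1 K.
    """

    base: SiteConditions
    n: int
    seed: int
    sigma_conc: float = 0.25
    sigma_pH: float = 0.1
    sigma_temperature: float = 1.0
    sigma_by_species: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        sigmas = [self.sigma_conc, self.sigma_pH, self.sigma_temperature,
                  *self.sigma_by_species.values()]
        if any(s < 0 for s in sigmas):
            raise ConfigError("perturbation sigmas must be >= 0")
        if self.n < 0:
            raise ConfigError("n must be >= 0")


def generate_scenarios(spec: ScenarioSpec) -> List[SiteConditions]:
    """Draw ``spec.n`` perturbed copies of the base conditions.

    Concentrations stay positive by construction (log-normal factors);
    pH is clipped to [0, 14].
    """
    rng = np.random.default_rng(spec.seed)
    out = []
    base = spec.base
    names = sorted(base.concentrations)
    for i in range(spec.n):
        conc = {}
        for name in names:
            sigma = spec.sigma_by_species.get(name, spec.sigma_conc)
            factor = float(np.exp(rng.normal(0.0, sigma))) if sigma else 1.0
            conc[name] = base.concentrations[name] * factor
        ph = base.pH + (float(rng.normal(0.0, spec.sigma_pH))
                        if spec.sigma_pH else 0.0)
        temp = base.temperature + (float(rng.normal(0.0, spec.sigma_temperature))
                                   if spec.sigma_temperature else 0.0)
        out.append(base.replace(
            site_name=f"{base.site_name}_{i:04d}",
            pH=min(14.0, max(0.0, ph)),
            temperature=max(temp, 1.0),
            concentrations=conc,
        ))
    return out


@dataclass(frozen=True)
class SyntheticSeqSpec:
    """Counts and layout for synthetic Grd/decoy protein sets."""

    n_grdb: int
    n_grdf: int
    n_decoy: int
    seed: int
    flank_range: Tuple[int, int] = (20, 80)
    selenocysteine_rate: float = 0.5
    gap_mode: str = "random"  # or "min": all gaps at their lower bound

    def __post_init__(self):
        if min(self.n_grdb, self.n_grdf, self.n_decoy) < 0:
            raise ConfigError("class counts must be >= 0")
        lo, hi = self.flank_range
        if not (0 <= lo <= hi):
            raise ConfigError("invalid flank range")
        if self.gap_mode not in ("random", "min"):
            raise ConfigError(f"unknown gap_mode {self.gap_mode!r}")


def _random_residues(rng: np.random.Generator, n: int) -> str:
    return "".join(AMINO_ACIDS[k] for k in rng.integers(0, len(AMINO_ACIDS),
                                                        size=n))


def instantiate_motif(pattern: MotifPattern, rng: np.random.Generator,
                      gap_mode: str = "random",
                      selenocysteine_rate: float = 0.0) -> str:
    """A concrete sequence satisfying every element of ``pattern``.

    ``gap_mode='min'`` pins every variable gap at its lower bound, giving
    the shortest legal instance (length == ``pattern.min_length``).
    Literal ``C`` positions become selenocysteine ``U`` with the given
    probability, exercising the U/C equivalence at catalytic anchors.
    """
    parts = []
    for el in pattern.elements:
        if isinstance(el, Gap):
            n = el.min if gap_mode == "min" else int(rng.integers(el.min,
                                                                  el.max + 1))
            parts.append(_random_residues(rng, n))
        elif isinstance(el, AnyOf):
            parts.append(el.residues[int(rng.integers(0, len(el.residues)))])
        else:
            res = el.residue
            if res == "C" and selenocysteine_rate and \
                    rng.random() < selenocysteine_rate:
                res = "U"
            parts.append(res)
    return "".join(parts)


def generate_grd_sequences(spec: SyntheticSeqSpec
                           ) -> Tuple[List[Tuple[str, str]],
                                      List[Tuple[str, str]]]:
    """Generate motif-bearing positives and shuffled decoys.

    Returns ``(records, labels)``: FASTA-ready (id, sequence) pairs in
    emission order, and (id, truth) rows for the sidecar TSV with truth
    in {GrdB-like, GrdF-like, non-Grd}.  GrdB positives are re-drawn in
    the (never observed in practice) event that they also satisfy the
    GrdF pattern, so construction guarantees the truth labels.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.flank_range
    records: List[Tuple[str, str]] = []
    labels: List[Tuple[str, str]] = []
    positives: List[str] = []

    def flank() -> str:
        return _random_residues(rng, int(rng.integers(lo, hi + 1)))

    for i in range(spec.n_grdb):
        for _ in range(100):
            core = instantiate_motif(GRDB_MOTIF, rng, spec.gap_mode,
                                     spec.selenocysteine_rate)
            seq = flank() + core + flank()
            if not match_motif(GRDF_MOTIF, seq).matched:
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not draw a GrdB-only positive")
        records.append((f"grdb_{i:04d}", seq))
        labels.append((f"grdb_{i:04d}", "GrdB-like"))
        positives.append(seq)
    for i in range(spec.n_grdf):
        core = instantiate_motif(GRDF_MOTIF, rng, spec.gap_mode,
                                 spec.selenocysteine_rate)
        seq = flank() + core + flank()
        records.append((f"grdf_{i:04d}", seq))
        labels.append((f"grdf_{i:04d}", "GrdF-like"))
        positives.append(seq)
    for i in range(spec.n_decoy):
        if positives:
            template = positives[int(rng.integers(0, len(positives)))]
        else:
            template = _random_residues(rng, int(rng.integers(300, 600)))
        shuffled = "".join(np.array(list(template))[
            rng.permutation(len(template))])
        records.append((f"decoy_{i:04d}", shuffled))
        labels.append((f"decoy_{i:04d}", "non-Grd"))
    return records, labels


def write_fasta(records: Sequence[Tuple[str, str]], path, width: int = 60
                ) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k:k + width] + "\n")


def write_labels(labels: Sequence[Tuple[str, str]], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["seq_id", "truth"])
        w.writerows(labels)
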