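"""Synthetic cohorts with the statistical structure the analysis assumes.

Real resting-state cohorts of this kind are restricted-access, so every
downstream stage is exercised on generated data instead. Each subject carries
a latent scalar trait g (standard normal, with a family-shared heritable
component so family-stratified cross-validation is meaningful) and a set of
confound variables whose population shared variance with g is controlled
exactly. Regional timeseries are stationary Gaussian AR(1) processes whose
*innovation* covariance is modulated by the trait,

    Sigma(g) = Sigma0 + g * effect_scale * Delta,

where Sigma0 carries a within-network baseline correlation and Delta plants
the trait effect on a known set of "salient" regions: cross-network region
pairs whose coupling grows with g, plus an innovation-variance modulation on
the same regions. The ground truth (which regions are salient, the full
Delta) is returned alongside the cohort so that saliency maps, ablation
statistics and whitened-innovation saliencies can all be checked against a
known answer.

The generator does not attempt hemodynamic forward modelling, motion or
physiological artifacts, or spatial geometry.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .preprocess import RegionTimeseries

__all__ = [
    "NetworkPartition",
    "CohortConfig",
    "GroundTruth",
    "SubjectRecord",
    "Cohort",
    "make_partition",
    "make_cohort",
    "simulate_timeseries",
    "simulate_cohort",
]


@dataclass
class NetworkPartition:
    """Assignment of every region to exactly one network."""

    region_ids: list[str]
    assignment: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.assignment) != set(self.region_ids):
            raise ValueError("every region must be assigned to exactly one network")
        if self.n_networks < 2:
            raise ValueError("need at least 2 networks")

    @property
    def networks(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.region_ids:
            seen.setdefault(self.assignment[r], None)
        return list(seen)

    @property
    def n_networks(self) -> int:
        return len(set(self.assignment.values()))

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.region_ids:
            n = self.assignment[r]
            out[n] = out.get(n, 0) + 1
        return out

    def members(self, network: str) -> list[str]:
        return [r for r in self.region_ids if self.assignment[r] == network]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("region_id\tnetwork_label\n")
            for r in self.region_ids:
                fh.write(f"{r}\t{self.assignment[r]}\n")

    @classmethod
    def from_tsv(cls, path) -> "NetworkPartition":
        region_ids, assignment = [], {}
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                r, n = line.rstrip("\n").split("\t")
                region_ids.append(r)
                assignment[r] = n
        return cls(region_ids, assignment)


def make_partition(
    n_regions: int,
    n_networks: int | None = None,
    seed: int = 0,
    sizes: list[int] | None = None,
    contiguous: bool = True,
) -> NetworkPartition:
    """Build a region->network partition.

    Either balanced (sizes differ by at most 1) for ``n_networks`` networks,
    or with explicit ``sizes``. Assignment is by contiguous blocks by default
    or by a seeded random shuffle of region order with ``contiguous=False``.
    """
    if sizes is not None:
        if sum(sizes) != n_regions:
            raise ValueError("explicit sizes must sum to n_regions")
        block_sizes = list(sizes)
    else:
        if n_networks is None:
            raise ValueError("give n_networks or explicit sizes")
        if not 2 <= n_networks <= n_regions:
            raise ValueError("need 2 <= n_networks <= n_regions")
        base, extra = divmod(n_regions, n_networks)
        block_sizes = [base + (1 if i < extra else 0) for i in range(n_networks)]
    region_ids = [f"r{i:03d}" for i in range(n_regions)]
    order = np.arange(n_regions)
    if not contiguous:
        order = np.random.default_rng([int(seed) & 0x7FFFFFFF, 11]).permutation(n_regions)
    assignment: dict[str, str] = {}
    pos = 0
    for j, size in enumerate(block_sizes):
        for i in order[pos : pos + size]:
            assignment[region_ids[i]] = f"net{j:02d}"
        pos += size
    return NetworkPartition(region_ids, assignment)


@dataclass(frozen=True)
class CohortConfig:
    """Generative conditions for one cohort.

    Full-scale defaults mirror the study design this emulates: 360 regions,
    1,200 timepoints per session at TR 0.72 s, 4 sessions, family sizes
    distributed as in the study's family table, and confounds sharing 13.8%
    of the trait variance. ``effect_scale`` is the magnitude of the
    g -> covariance effect; ``salient_fraction`` the fraction of regions
    carrying it. Desk-scale analyses use :meth:`desk_scale`.
    """

    n_subjects: int
    n_regions: int = 360
    n_timepoints: int = 1200
    n_sessions: int = 4
    tr: float = 0.72
    family_size_probs: tuple[tuple[int, float], ...] = ((1, 0.28), (2, 0.38), (3, 0.34))
    confound_r2: float = 0.138
    n_confounds: int = 5
    effect_scale: float = 0.2
    salient_fraction: float = 0.2
    ar_coefficient: float = 0.4
    heritability: float = 0.5
    baseline_within: float = 0.3
    variance_effect: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_subjects, self.n_regions, self.n_timepoints,
                  self.n_sessions, self.n_confounds)
        if min(counts) < 1:
            raise ValueError("all counts must be positive")
        if not 0 <= self.confound_r2 < 1:
            raise ValueError("confound_r2 must lie in [0, 1)")
        if self.effect_scale < 0:
            raise ValueError("effect_scale must be non-negative")
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if not 0 <= self.heritability <= 1:
            raise ValueError("heritability must lie in [0, 1]")
        probs = dict(self.family_size_probs)
        if abs(sum(probs.values()) - 1.0) > 1e-9 or min(probs.values()) < 0:
            raise ValueError("family_size_probs must be a distribution")

    @classmethod
    def desk_scale(cls, n_subjects: int = 300, seed: int = 0, **overrides) -> "CohortConfig":
        base = dict(
            n_subjects=n_subjects,
            n_regions=60,
            n_timepoints=400,
            n_sessions=2,
            seed=seed,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class GroundTruth:
    """Planted effect: which regions carry trait signal and how."""

    salient_regions: list[str]
    delta_matrix: np.ndarray
    confound_coefficients: np.ndarray
    sigma0: np.ndarray

    def __post_init__(self) -> None:
        D = np.asarray(self.delta_matrix, dtype=float)
        if not np.allclose(D, D.T):
            raise ValueError("delta_matrix must be symmetric")
        self.delta_matrix = D

    def salient_mask(self, region_ids: list[str]) -> np.ndarray:
        sal = set(self.salient_regions)
        return np.array([r in sal for r in region_ids], dtype=bool)

    def to_json(self, path) -> None:
        payload = {
            "salient_regions": self.salient_regions,
            "delta_matrix": self.delta_matrix.tolist(),
            "confound_coefficients": np.asarray(self.confound_coefficients).tolist(),
            "sigma0": np.asarray(self.sigma0).tolist(),
        }
        Path(path).write_text(json.dumps(payload))


@dataclass
class SubjectRecord:
    subject_id: str
    family_id: str
    g: float
    confounds: np.ndarray
    sessions: list[RegionTimeseries] = field(default_factory=list)


@dataclass
class Cohort:
    config: CohortConfig
    partition: NetworkPartition
    subjects: list[SubjectRecord]
    truth: GroundTruth

    @property
    def region_ids(self) -> list[str]:
        return self.partition.region_ids

    def g_vector(self) -> np.ndarray:
        return np.array([s.g for s in self.subjects])

    def confound_matrix(self) -> np.ndarray:
        return np.stack([s.confounds for s in self.subjects])


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *key])


def _draw_family_sizes(rng, n_subjects: int, probs: dict[int, float]) -> list[int]:
    sizes: list[int] = []
    total = 0
    groups = sorted(probs)
    p = np.array([probs[k] for k in groups])
    while total < n_subjects:
        k = int(rng.choice(groups, p=p))
        if k >= 3:  # "3+" group: 3 or 4 members
            k = 3 + int(rng.integers(0, 2))
        k = min(k, n_subjects - total)
        sizes.append(k)
        total += k
    return sizes


def _build_truth(config: CohortConfig, partition: NetworkPartition, rng) -> GroundTruth:
    R = config.n_regions
    region_ids = partition.region_ids
    n_sal = max(2, int(round(config.salient_fraction * R)))
    n_sal -= n_sal % 2  # paired couplings
    net_of = np.array([partition.assignment[r] for r in region_ids])

    # draw salient pairs spanning different networks, so the planted coupling
    # sits on a zero-baseline correlation and Sigma(g) stays well conditioned
    perm = rng.permutation(R)
    chosen: list[int] = []
    pairs: list[tuple[int, int]] = []
    used = np.zeros(R, dtype=bool)
    for i in perm:
        if len(pairs) * 2 >= n_sal:
            break
        if used[i]:
            continue
        partner = next(
            (j for j in perm if not used[j] and j != i and net_of[j] != net_of[i]), None
        )
        if partner is None:
            continue
        used[i] = used[partner] = True
        pairs.append((int(i), int(partner)))
        chosen += [int(i), int(partner)]

    delta = np.zeros((R, R))
    for i, j in pairs:
        delta[i, j] = delta[j, i] = 1.0
        delta[i, i] = delta[j, j] = config.variance_effect

    sigma0 = np.eye(R)
    for net in partition.networks:
        idx = [region_ids.index(r) for r in partition.members(net)]
        for a in idx:
            for b in idx:
                if a != b:
                    sigma0[a, b] = config.baseline_within

    k = config.n_confounds
    r2 = config.confound_r2
    w = np.sqrt(r2 / (k * (1.0 - r2) + r2)) if r2 > 0 else 0.0
    coeffs = np.full(k, w)
    salient = sorted(region_ids[i] for i in chosen)
    return GroundTruth(salient, delta, coeffs, sigma0)


def make_cohort(
    config: CohortConfig, partition: NetworkPartition | None = None
) -> Cohort:
    """Draw subjects (trait, families, confounds) and the planted ground truth.

    Timeseries are not attached; call :func:`simulate_timeseries` per subject
    or :func:`simulate_cohort` for everything at once.
    """
    if partition is None:
        partition = make_partition(config.n_regions, max(2, config.n_regions // 10))
    if len(partition.region_ids) != config.n_regions:
        raise ValueError("partition size does not match n_regions")
    rng = _rng(config.seed, 0)
    truth = _build_truth(config, partition, _rng(config.seed, 1))

    sizes = _draw_family_sizes(rng, config.n_subjects, dict(config.family_size_probs))
    h = config.heritability
    subjects: list[SubjectRecord] = []
    sid = 0
    for fam_idx, fam_size in enumerate(sizes):
        shared = rng.standard_normal()
        for _ in range(fam_size):
            g = np.sqrt(h) * shared + np.sqrt(1.0 - h) * rng.standard_normal()
            noise = rng.standard_normal(config.n_confounds)
            w = truth.confound_coefficients
            confounds = w * g + np.sqrt(1.0 - w**2) * noise
            subjects.append(
                SubjectRecord(
                    subject_id=f"s{sid:05d}",
                    family_id=f"f{fam_idx:05d}",
                    g=float(g),
                    confounds=confounds,
                )
            )
            sid += 1
    return Cohort(config, partition, subjects, truth)


def _sigma_for(g: float, truth: GroundTruth, config: CohortConfig,
               subject_id: str) -> np.ndarray:
    sigma = truth.sigma0 + g * config.effect_scale * truth.delta_matrix
    w, V = np.linalg.eigh(sigma)
    if w.min() < 1e-8:
        warnings.warn(
            f"covariance for subject {subject_id} (g={g:.2f}) projected to PSD",
            RuntimeWarning,
            stacklevel=3,
        )
        sigma = (V * np.clip(w, 1e-8, None)) @ V.T
    return sigma


def simulate_timeseries(
    subject: SubjectRecord,
    truth: GroundTruth,
    config: CohortConfig,
    n_timepoints: int | None = None,
) -> list[RegionTimeseries]:
    """Generate the subject's sessions: AR(1)-filtered correlated innovations.

    Innovations e_t ~ N(0, Sigma(g)); x_t = a x_{t-1} + e_t started from its
    stationary distribution, so the series is stationary and its correlation
    matrix equals the correlation of Sigma(g). Sessions are independent given
    the subject. If Sigma(g) has eigenvalues below 1e-8 it is projected to the
    nearest PSD matrix with a warning naming the subject.
    """
    T = n_timepoints if n_timepoints is not None else config.n_timepoints
    sigma = _sigma_for(subject.g, truth, config, subject.subject_id)
    L = np.linalg.cholesky(sigma + 1e-12 * np.eye(sigma.shape[0]))
    a = config.ar_coefficient
    sidx = int(subject.subject_id.lstrip("s"))
    sessions = []
    for s in range(config.n_sessions):
        rng = _rng(config.seed, 2, sidx, s)
        innov = rng.standard_normal((T, sigma.shape[0])) @ L.T
        if a > 0:
            innov[0] /= np.sqrt(1.0 - a * a)  # stationary start
            x = lfilter([1.0], [1.0, -a], innov, axis=0)
        else:
            x = innov
        sessions.append(
            RegionTimeseries(x, tr=config.tr, region_ids=_region_ids(sigma.shape[0]))
        )
    return sessions


def _region_ids(n_regions: int) -> list[str]:
    # canonical labelling, shared with make_partition
    return [f"r{i:03d}" for i in range(n_regions)]


def simulate_cohort(
    config: CohortConfig, partition: NetworkPartition | None = None
) -> Cohort:
    """Full generation: subjects, ground truth and all session timeseries."""
    cohort = make_cohort(config, partition)
    for subj in cohort.subjects:
        subj.sessions = simulate_timeseries(subj, cohort.truth, config)
    return cohort


def save_cohort(cohort: Cohort, directory) -> None:
    """Write metadata TSV, per-session matrices, partition TSV and truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cohort.partition.to_tsv(directory / "partition.tsv")
    cohort.truth.to_json(directory / "ground_truth.json")
    k = cohort.config.n_confounds
    s = cohort.config.n_sessions
    header = (
        ["subject_id", "family_id", "g"]
        + [f"confound_{i+1}" for i in range(k)]
        + [f"session_{j+1}" for j in range(s)]
    )
    with open(directory / "metadata.tsv", "w") as fh:
        fh.write("\t".join(header) + "\n")
        for subj in cohort.subjects:
            paths = []
            for j, sess in enumerate(subj.sessions):
                rel = f"{subj.subject_id}_session{j+1}.tsv"
                np.savetxt(
                    directory / rel,
                    sess.values,
                    delimiter="\t",
                    header="\t".join(sess.region_ids),
                    comments="",
                )
                paths.append(rel)
            row = (
                [subj.subject_id, subj.family_id, f"{subj.g:.10g}"]
                + [f"{c:.10g}" for c in subj.confounds]
                + paths
            )
            fh.write("\t".join(row) + "\n")
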