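"""Synthetic resting-state cohorts with a planted connectivity-symptom effect.

Every downstream stage of the package is testable without any imaging data:
this module generates complete cohorts — parcellated BOLD time series,
rigid-body motion traces with designed spikes, nuisance signals, CES-D item
responses, demographics — whose statistical structure matches what the
analysis assumes.

The generative model, per subject j with standardized latent symptom
severity s_j:

* The region covariance is block structured: unit diagonal, within-network
  off-diagonal w_k for network k, and a common between-network level b —
  except that one designated *effect network* has its between-network
  entries set to the subject's realized coupling

      b_j = b + beta * s_j + sigma_b * eps_j .

  With beta < 0 the cohort carries a negative association between the
  effect network's between-network connectivity and symptom severity, the
  effect the pipeline is meant to recover.  The matrix is repaired to
  positive definiteness by clipping eigenvalues and rescaling to unit
  diagonal; the repair must not move any target entry by more than 0.05.

* Frames are drawn i.i.d. from the resulting multivariate normal law (no
  temporal autocorrelation; an optional AR(1) coefficient is available).
  A scaled common "global" component is added to every region and mixed
  into the ventricle / white-matter nuisance signals, so that global-signal
  regression is exercised end to end.

* Motion is a smooth low-amplitude drift plus isolated large translation
  steps whose framewise displacement exceeds the scrubbing threshold; the
  designed spike frames are returned so tests can verify censoring.

* CES-D items follow a graded-threshold model: item propensity is
  loading * s_j plus unit normal noise, cut at fixed thresholds into
  levels 0-3; reverse-worded items store the flipped response so scoring
  inverts them correctly.

All randomness derives from a single integer seed through spawned
``numpy.random.SeedSequence`` streams, so a configuration determines every
output bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .connectivity import NetworkPartition, fc_matrix, bgc_profile
from .preprocess import ParcellatedTimeSeries
from .symptoms import DEFAULT_REVERSE_ITEMS, score_cesd

__all__ = [
    "SimulationConfig",
    "ItemModel",
    "SubjectData",
    "SyntheticCohort",
    "make_partition",
    "build_block_covariance",
    "repair_positive_definite",
    "simulate_subject_timeseries",
    "simulate_motion",
    "simulate_cesd_items",
    "simulate_cohort",
    "quick_bgc_cohort",
    "DEFAULT_NETWORK_NAMES",
]

#: The 12 functional-network labels used by the default full-scale partition.
DEFAULT_NETWORK_NAMES = (
    "Visual 1",
    "Visual 2",
    "Somatomotor",
    "Cingulo-opercular",
    "Language",
    "Default mode",
    "Fronto-parietal",
    "Auditory",
    "Posterior multimodal",
    "Dorsal attention",
    "Ventral multimodal",
    "Orbito-affective",
)

#: Default planted effect slope.  Calibrated once by simulation so that the
#: population correlation between effect-network BGC and the Box-Cox CES-D
#: total is approximately -0.25 under the scaled-down geometry (4 networks
#: of 15 regions, 600 frames), the effect size the analysis is designed to
#: detect at n ~ 100.
DEFAULT_EFFECT_BETA = -0.0043


@dataclass(frozen=True)
class ItemModel:
    """Graded-threshold response model for the 20 CES-D items."""

    loadings: tuple = (0.9,) * 20
    cutpoints: tuple = (-0.35, 0.9, 2.0)
    reverse_items: tuple = DEFAULT_REVERSE_ITEMS

    def __post_init__(self):
        if len(self.loadings) != 20:
            raise ValueError("need 20 item loadings")
        if not np.all(np.isfinite(self.loadings)):
            raise ValueError("loadings must be finite")
        if list(self.cutpoints) != sorted(self.cutpoints):
            raise ValueError("cutpoints must be increasing")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the emulated study: 96 subjects, 360 regions in 12
    networks, 1,070 frames at TR = 0.785 s, and a planted negative effect
    on the fronto-parietal analog network.
    """

    n_subjects: int = 96
    network_sizes: tuple = (30,) * 12
    network_names: tuple = DEFAULT_NETWORK_NAMES
    n_frames: int = 1070
    tr: float = 0.785
    within_corr: float = 0.3
    between_corr_base: float = 0.05
    effect_network: str = "Fronto-parietal"
    effect_beta: float = DEFAULT_EFFECT_BETA
    coupling_noise_sd: float = 0.01
    global_amp: float = 0.3
    motion_spike_rate: float = 0.01
    ar_coef: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 4:
            raise ValueError("need at least 4 subjects")
        if len(self.network_sizes) != len(self.network_names):
            raise ValueError("network_sizes and network_names length mismatch")
        if any(s < 2 for s in self.network_sizes):
            raise ValueError("each network needs at least 2 regions")
        if not (-1 < self.within_corr < 1 and -1 < self.between_corr_base < 1):
            raise ValueError("correlations must lie in (-1, 1)")
        if self.n_frames < 10:
            raise ValueError("need at least 10 frames")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not (0 <= self.motion_spike_rate < 1):
            raise ValueError("spike rate must lie in [0, 1)")
        if self.effect_network not in self.network_names:
            raise ValueError("effect_network must be one of network_names")
        if not (0 <= self.ar_coef < 1):
            raise ValueError("ar_coef must lie in [0, 1)")

    @classmethod
    def scaled_down(cls, **overrides) -> "SimulationConfig":
        """Reduced geometry (4 networks x 15 regions, 600 frames) that keeps
        every code path while running in seconds."""
        defaults = dict(
            network_sizes=(15, 15, 15, 15),
            network_names=(
                "Fronto-parietal",
                "Default mode",
                "Language",
                "Somatomotor",
            ),
            n_frames=600,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @property
    def n_total(self) -> int:
        return int(sum(self.network_sizes))

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("network_sizes", "network_names"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for k in ("network_sizes", "network_names"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass(frozen=True)
class SubjectData:
    subject_id: str
    timeseries: ParcellatedTimeSeries
    motion: np.ndarray
    spike_frames: tuple
    nuisance: pd.DataFrame


@dataclass(frozen=True)
class SyntheticCohort:
    config: SimulationConfig
    partition: NetworkPartition
    subjects: tuple
    severity: np.ndarray
    couplings: np.ndarray
    metadata: pd.DataFrame

    def write(self, outdir: str | Path) -> Path:
        """Write the cohort in the pipeline's file formats; returns the
        manifest path.  Ground-truth severity/couplings go to a clearly
        labelled sidecar so analysis code cannot confuse them with data."""
        from . import io as nio

        outdir = Path(outdir)
        (outdir / "subjects").mkdir(parents=True, exist_ok=True)
        nio.write_partition(outdir / "partition.tsv", self.partition)
        nio.write_metadata(outdir / "metadata.tsv", self.metadata)
        rows = []
        for s in self.subjects:
            tsp = outdir / "subjects" / f"{s.subject_id}_timeseries.tsv"
            mop = outdir / "subjects" / f"{s.subject_id}_motion.tsv"
            nup = outdir / "subjects" / f"{s.subject_id}_nuisance.tsv"
            nio.write_timeseries(tsp, s.timeseries)
            nio.write_motion(mop, s.motion)
            nio.write_nuisance(nup, s.nuisance)
            rows.append(
                (
                    s.subject_id,
                    tsp.relative_to(outdir).as_posix(),
                    mop.relative_to(outdir).as_posix(),
                    nup.relative_to(outdir).as_posix(),
                )
            )
        manifest = pd.DataFrame(
            rows,
            columns=["subject_id", "timeseries_path", "motion_path", "nuisance_path"],
        )
        manifest_path = outdir / "manifest.tsv"
        manifest.to_csv(manifest_path, sep="\t", index=False)
        truth = pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "latent_severity": self.severity,
                "realized_coupling": self.couplings,
            }
        )
        truth.to_csv(outdir / "synthetic_ground_truth.tsv", sep="\t", index=False)
        with open(outdir / "cohort.yaml", "w") as fh:
            yaml.safe_dump(
                {"tr": self.config.tr, "config": self.config.to_dict()}, fh
            )
        return manifest_path


def make_partition(
    network_sizes: Sequence[int], network_names: Sequence
) -> NetworkPartition:
    """Contiguous region ids 0..N-1 assigned to networks of given sizes."""
    if len(network_sizes) != len(network_names):
        raise ValueError("network_sizes and network_names length mismatch")
    if len(set(network_names)) != len(network_names):
        raise ValueError("duplicate network names")
    if any(s < 1 for s in network_sizes):
        raise ValueError("empty network")
    labels: list = []
    for size, name in zip(network_sizes, network_names):
        labels.extend([name] * int(size))
    n = len(labels)
    width = max(3, len(str(n - 1)))
    region_ids = tuple(f"R{i:0{width}d}" for i in range(n))
    return NetworkPartition(region_ids, tuple(labels))


def repair_positive_definite(
    sigma: np.ndarray, eps: float = 1e-6, max_change: float = 0.05
) -> np.ndarray:
    """Clip eigenvalues at ``eps`` and rescale to unit diagonal.

    The smallest intervention that preserves the block structure; raises if
    any entry moves by more than ``max_change`` from its target value.
    """
    sigma = np.asarray(sigma, dtype=float)
    w, v = np.linalg.eigh(sigma)
    if w.min() >= eps:
        return sigma
    w = np.clip(w, eps, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    drift = np.abs(fixed - sigma).max()
    if drift > max_change:
        raise ValueError(
            f"positive-definiteness repair moved an entry by {drift:.3g} "
            f"(> {max_change}); target correlations are infeasible"
        )
    return fixed


def build_block_covariance(
    partition: NetworkPartition,
    within_corr: float,
    between_corr: float,
    effect_network: str | None = None,
    effect_coupling: float | None = None,
) -> np.ndarray:
    """Block-structured correlation matrix for one subject.

    Within-network off-diagonals are ``within_corr``, between-network
    entries ``between_corr``, except rows/columns of ``effect_network``
    which take ``effect_coupling``.  Repaired to positive definiteness.
    """
    if effect_coupling is not None and abs(effect_coupling) >= 1:
        raise ValueError("effect coupling must have magnitude < 1")
    n = partition.n_total
    sigma = np.full((n, n), float(between_corr))
    for net in partition.networks:
        idx = partition.indices(net)
        sigma[np.ix_(idx, idx)] = within_corr
    if effect_network is not None:
        rows = partition.indices(effect_network)
        labels = np.asarray(partition.network_of, dtype=object)
        others = np.flatnonzero(labels != effect_network)
        sigma[np.ix_(rows, others)] = effect_coupling
        sigma[np.ix_(others, rows)] = effect_coupling
    np.fill_diagonal(sigma, 1.0)
    return repair_positive_definite(sigma)


def simulate_subject_timeseries(
    partition: NetworkPartition,
    coupling: float,
    config: SimulationConfig,
    subject_seed: int,
    subject_id: str = "sub-000",
) -> tuple[ParcellatedTimeSeries, pd.DataFrame]:
    """Sample one subject's BOLD matrix plus nuisance signals.

    Returns the time series (with the global component mixed in) and a
    DataFrame with columns ventricle, white_matter, global.
    """
    rng = np.random.default_rng(subject_seed)
    sigma = build_block_covariance(
        partition,
        config.within_corr,
        config.between_corr_base,
        config.effect_network,
        coupling,
    )
    chol = np.linalg.cholesky(sigma)
    n, t = partition.n_total, config.n_frames
    innov = rng.standard_normal((n, t))
    if config.ar_coef > 0:
        phi = config.ar_coef
        innov = innov * np.sqrt(1 - phi**2)
        for k in range(1, t):
            innov[:, k] += phi * innov[:, k - 1]
        innov[:, 0] /= np.sqrt(1 - phi**2)  # stationary start
    z = chol @ innov
    g = rng.standard_normal(t)
    data = z + config.global_amp * g
    ventricle = 0.7 * g + 0.5 * rng.standard_normal(t)
    white_matter = 0.7 * g + 0.5 * rng.standard_normal(t)
    nuisance = pd.DataFrame(
        {
            "ventricle": ventricle,
            "white_matter": white_matter,
            "global": data.mean(axis=0),
        }
    )
    ts = ParcellatedTimeSeries(
        subject_id, data, config.tr, tuple(partition.region_ids)
    )
    return ts, nuisance


def simulate_motion(
    config: SimulationConfig, subject_seed: int
) -> tuple[np.ndarray, tuple]:
    """Smooth drift plus isolated high-FD translation steps.

    Returns (frames x 6 motion matrix, designed spike frames).  Spike
    amplitudes (1.2-2.0 mm) are chosen so that the framewise displacement
    exceeds the 0.3 mm scrubbing threshold even after the 0.3 Hz low-pass
    of the FD trace.
    """
    rng = np.random.default_rng(subject_seed)
    t = config.n_frames
    steps = rng.normal(0.0, 0.001, size=(t, 6))
    steps[:, 3:] /= 50.0  # rotations in radians; arc length at 50 mm matches
    steps[0] = 0.0
    motion = np.cumsum(steps, axis=0)
    spikes = []
    if config.motion_spike_rate > 0:
        flags = rng.random(t - 1) < config.motion_spike_rate
        for f in np.flatnonzero(flags) + 1:
            amp = rng.uniform(1.2, 2.0) * rng.choice([-1.0, 1.0])
            axis = rng.integers(0, 3)
            motion[f:, axis] += amp
            spikes.append(int(f))
    return motion, tuple(spikes)


def simulate_cesd_items(
    latent_severity: float,
    item_model: ItemModel = ItemModel(),
    subject_seed: int = 0,
) -> np.ndarray:
    """20 item responses in {0..3} from the graded-threshold model.

    The *scored* level (after reverse-item inversion) is monotone in
    severity in expectation; reverse-worded items store 3 - level so the
    scoring stage has real inversions to perform.
    """
    rng = np.random.default_rng(subject_seed)
    prop = np.asarray(item_model.loadings) * latent_severity + rng.standard_normal(20)
    cut = np.asarray(item_model.cutpoints)
    level = (prop[:, None] > cut[None, :]).sum(axis=1)
    resp = level.copy()
    for i in item_model.reverse_items:
        resp[i - 1] = 3 - level[i - 1]
    return resp.astype(int)


def _subject_seeds(config: SimulationConfig) -> tuple:
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_subjects + 1)
    per_subject = [tuple(int(x) for x in c.generate_state(3)) for c in
                   children[: config.n_subjects]]
    cohort_rng = np.random.default_rng(children[-1])
    return per_subject, cohort_rng


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Full synthetic cohort: time series, motion, nuisance, phenotypes."""
    partition = make_partition(config.network_sizes, config.network_names)
    seeds, cohort_rng = _subject_seeds(config)
    n = config.n_subjects
    s = cohort_rng.standard_normal(n)
    s = (s - s.mean()) / s.std()
    couplings = (
        config.between_corr_base
        + config.effect_beta * s
        + config.coupling_noise_sd * cohort_rng.standard_normal(n)
    )
    if np.any(np.abs(couplings) >= 1):
        raise ValueError("realized coupling out of (-1, 1); reduce effect size")
    ages = np.round(cohort_rng.uniform(18, 35, size=n), 1)
    genders = np.array(["F"] * (n // 2) + ["M"] * (n - n // 2), dtype=object)
    cohort_rng.shuffle(genders)
    hand_levels = np.array([2, 1, 0, -1, -2])
    hand_probs = np.array([0.70, 0.20, 0.05, 0.03, 0.02])

    subjects = []
    items_rows = []
    hands_rows = []
    for j in range(n):
        sid = f"sub-{j:03d}"
        ts_seed, mo_seed, it_seed = seeds[j]
        ts, nuis = simulate_subject_timeseries(
            partition, float(couplings[j]), config, ts_seed, sid
        )
        motion, spikes = simulate_motion(config, mo_seed)
        items = simulate_cesd_items(float(s[j]), ItemModel(), it_seed)
        hands = np.random.default_rng(it_seed + 1).choice(
            hand_levels, size=11, p=hand_probs
        )
        subjects.append(SubjectData(sid, ts, motion, spikes, nuis))
        items_rows.append(items)
        hands_rows.append(hands)

    meta = pd.DataFrame(
        {
            "subject_id": [sub.subject_id for sub in subjects],
            "age": ages,
            "gender": genders,
        }
    )
    items_arr = np.asarray(items_rows)
    for i in range(20):
        meta[f"cesd_{i + 1:02d}"] = items_arr[:, i]
    hands_arr = np.asarray(hands_rows)
    for i in range(11):
        meta[f"hand_{i + 1:02d}"] = hands_arr[:, i]
    return SyntheticCohort(config, partition, tuple(subjects), s, couplings, meta)


def quick_bgc_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Network BGC and scored CES-D totals, skipping the motion/nuisance path.

    Draws the same per-subject couplings and item responses as
    :func:`simulate_cohort` but computes FC directly on the clean block
    samples (no global mixing, no motion).  Intended for statistical
    calibration studies of the generator itself — type-I error and effect
    monotonicity — where thousands of cohorts are needed; the full pipeline
    remains the reference path for end-to-end checks.
    """
    partition = make_partition(config.network_sizes, config.network_names)
    seeds, cohort_rng = _subject_seeds(config)
    n = config.n_subjects
    s = cohort_rng.standard_normal(n)
    s = (s - s.mean()) / s.std()
    couplings = (
        config.between_corr_base
        + config.effect_beta * s
        + config.coupling_noise_sd * cohort_rng.standard_normal(n)
    )
    net_rows = {net: [] for net in partition.networks}
    totals = np.empty(n)
    for j in range(n):
        ts_seed, _, it_seed = seeds[j]
        rng = np.random.default_rng(ts_seed)
        sigma = build_block_covariance(
            partition,
            config.within_corr,
            config.between_corr_base,
            config.effect_network,
            float(couplings[j]),
        )
        data = np.linalg.cholesky(sigma) @ rng.standard_normal(
            (partition.n_total, config.n_frames)
        )
        prof = bgc_profile(fc_matrix(data, partition.region_ids), partition)
        for net in partition.networks:
            net_rows[net].append(prof.network_bgc[net])
        items = simulate_cesd_items(float(s[j]), ItemModel(), it_seed)
        totals[j] = score_cesd(items).total
    bgc = pd.DataFrame(net_rows).T
    bgc.columns = [f"sub-{j:03d}" for j in range(n)]
    return bgc, totals
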