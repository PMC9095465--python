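"""Synthetic resting-state cohorts with known ground truth.

This module generates everything the downstream connectome analysis
consumes: a parcel atlas with network labels and spatial centroids, a
phenotype table (group, age, sex, head motion, clinical scores), and
per-subject parcellated BOLD time series.  The generator's job is to
reproduce the *statistical structure* the analysis assumes, not BOLD
physiology:

* block-modular covariance — parcels within a functional network are
  more strongly correlated than parcels in different networks;
* group structure — a designated ("UC-like") group receives a global
  connectivity offset and a planted subnetwork of strengthened edges;
* temporal non-stationarity — each subject switches between covariance
  states with a geometric dwell time, so that windowed connectivity
  fluctuates more for fast switchers.  A per-subject ``stability_param``
  in [0, 1] maps monotonically to dwell length;
* clinical scores generated as linear functions of ``stability_param``
  plus Gaussian noise.

Samples are plain zero-mean multivariate Gaussian draws: the analysis
consumes second-order statistics only, so hemodynamic convolution and
band-pass structure are deliberately absent.  All ground truth (planted
edges, covariance parameters, per-subject stability, score loadings) is
recorded so recovery tests can score the analysis against it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_NETWORK_NAMES",
    "ParcelAtlas",
    "ParcelTimeSeries",
    "CohortGroundTruth",
    "CohortConfig",
    "GenerationError",
    "generate_atlas",
    "make_group_covariance",
    "simulate_subject",
    "generate_cohort",
    "write_atlas_tsv",
    "read_atlas_tsv",
    "write_timeseries_tsv",
    "read_timeseries_tsv",
    "write_phenotypes_tsv",
    "read_phenotypes_tsv",
    "write_ground_truth_json",
]

#: Default coarse cortical network labels (8-network scheme).
DEFAULT_NETWORK_NAMES = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "salience_ventral_attention",
    "limbic",
    "control",
    "default",
    "temporal_parietal",
)

#: Spacing (mm) of the lattice on which network centers are placed.
_CENTER_SPACING = 55.0
#: Isotropic centroid jitter (mm, sd per axis) within a network.
_CENTROID_JITTER = 8.0


class GenerationError(RuntimeError):
    """Raised when a requested synthetic object cannot be generated."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParcelAtlas:
    """Parcel lookup table: id, name, network label, MNI-style centroid (mm)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"parcel_id", "parcel_name", "network_label", "x", "y", "z"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"atlas table missing columns: {sorted(missing)}")
        ids = np.asarray(self.table["parcel_id"])
        if not np.array_equal(ids, np.arange(len(ids))):
            raise ValueError("parcel_ids must be 0..N-1 with no gaps")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("atlas centroids must be finite")

    @property
    def n_parcels(self) -> int:
        return len(self.table)

    @property
    def centroids(self) -> np.ndarray:
        return self.table[["x", "y", "z"]].to_numpy(dtype=float)

    @property
    def network_labels(self) -> np.ndarray:
        return self.table["network_label"].to_numpy()


@dataclass(frozen=True)
class ParcelTimeSeries:
    """One subject's T x N parcel-averaged BOLD matrix with its TR."""

    subject_id: str
    data: np.ndarray
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
            raise ValueError("time series must be T x N with T >= 2, N >= 2")
        if np.isnan(data).any():
            raise ValueError("time series contains NaN")
        if np.any(data.var(axis=0) <= 0):
            bad = int(np.flatnonzero(data.var(axis=0) <= 0)[0])
            raise ValueError(f"parcel {bad} has zero variance")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]


@dataclass
class CohortGroundTruth:
    """Everything the generator knows that the analysis must recover."""

    planted_component_edges: frozenset
    group_covariance_params: dict
    stability_param: dict  # subject_id -> scalar in [0, 1]
    score_loadings: dict  # score -> (intercept, slope, noise_sd)

    def to_json_dict(self) -> dict:
        return {
            "planted_component_edges": sorted(map(list, self.planted_component_edges)),
            "group_covariance_params": self.group_covariance_params,
            "stability_param": self.stability_param,
            "score_loadings": {k: list(v) for k, v in self.score_loadings.items()},
        }


# score -> (intercept, slope on stability_param, noise sd).  Slopes are sized
# so that within-group correlations with stability sit near the r ~ 0.3 range
# typical of questionnaire-brain associations; the SF-12 mental component
# loads negatively (worse mental health with higher cortical stability).
_DEFAULT_SCORE_LOADINGS = {
    "pss": (12.0, 8.0, 4.0),
    "hads_anxiety": (5.0, 4.0, 2.5),
    "hads_depression": (3.0, 4.0, 2.5),
    "stai_state": (32.0, 10.0, 6.0),
    "stai_trait": (33.0, 12.0, 6.0),
    "sf12_mcs": (52.0, -12.0, 7.0),
}


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the study design: three age- and sex-matched groups
    (HC, IBS, UC) of 74 subjects each, 400 parcels in 8 coarse networks,
    300 volumes at TR = 2 s.  The UC-like group (the last entry of
    ``groups``) receives a global connectivity offset, a planted
    strengthened subnetwork, and the highest mean stability parameter
    (longest state dwell, hence the most stable windowed connectivity).
    """

    n_per_group: int = 74
    groups: tuple = ("HC", "IBS", "UC")
    n_parcels: int = 400
    n_networks: int = 8
    n_timepoints: int = 300
    tr_seconds: float = 2.0
    within_r: float = 0.35
    between_r: float = 0.08
    group_fc_offset: Mapping[str, float] = field(
        default_factory=lambda: {"HC": 0.0, "IBS": 0.0, "UC": 0.04}
    )
    planted_delta: Mapping[str, float] = field(
        default_factory=lambda: {"HC": 0.0, "IBS": 0.0, "UC": 0.12}
    )
    n_planted_nodes: int = 10
    state_contrast: float = 1.0  # blend weight of the alternative state
    stability_mean: Mapping[str, float] = field(
        default_factory=lambda: {"HC": 0.38, "IBS": 0.50, "UC": 0.64}
    )
    stability_sd: float = 0.12
    dwell_range: tuple = (20.0, 5000.0)
    age_range: tuple = (20.0, 60.0)
    sex_p_female: float = 0.5
    mean_fd_mean: float = 0.16
    mean_fd_sd: float = 0.06
    score_loadings: Mapping[str, tuple] = field(
        default_factory=lambda: dict(_DEFAULT_SCORE_LOADINGS)
    )

    @classmethod
    def null(cls, **overrides) -> "CohortConfig":
        """A configuration with every group effect switched off."""
        base = dict(
            group_fc_offset={},
            planted_delta={},
            stability_mean={},
            score_loadings={
                name: (inter, 0.0, sd)
                for name, (inter, _s, sd) in _DEFAULT_SCORE_LOADINGS.items()
            },
        )
        base.update(overrides)
        cfg = cls(**base)
        cfg.group_fc_offset = {g: 0.0 for g in cfg.groups}
        cfg.planted_delta = {g: 0.0 for g in cfg.groups}
        cfg.stability_mean = {g: 0.5 for g in cfg.groups}
        return cfg


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------


def _lattice_points(k: int) -> np.ndarray:
    """First k points of the integer lattice sorted by (norm, x, y, z)."""
    r = 1
    while (2 * r + 1) ** 3 < k + 1:
        r += 1
    axis = np.arange(-r, r + 1)
    pts = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"), axis=-1).reshape(-1, 3)
    norms = np.linalg.norm(pts, axis=1)
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0], norms))
    return pts[order][:k].astype(float)


def generate_atlas(
    n_parcels: int,
    n_networks: int = 8,
    seed: int = 0,
    network_names: Sequence[str] | None = None,
) -> ParcelAtlas:
    """Generate a parcel atlas with contiguous network blocks and clustered centroids.

    Parcels are assigned to networks in contiguous blocks of near-equal
    size.  Network centers sit on a 55 mm lattice (so inter-network
    centroid distances span the short / middle / long wiring bins for
    three or more networks) and parcel centroids add isotropic Gaussian
    jitter around their network's center.
    """
    if n_parcels < 1 or n_networks < 1:
        raise ValueError("n_parcels and n_networks must be positive")
    if n_parcels < n_networks:
        raise ValueError("need at least one parcel per network")
    if network_names is None:
        if n_networks <= len(DEFAULT_NETWORK_NAMES):
            network_names = DEFAULT_NETWORK_NAMES[:n_networks]
        else:
            extra = [f"network_{i}" for i in range(len(DEFAULT_NETWORK_NAMES), n_networks)]
            network_names = list(DEFAULT_NETWORK_NAMES) + extra
    if len(network_names) != n_networks:
        raise ValueError("network_names length must equal n_networks")

    rng = np.random.default_rng(seed)
    blocks = np.array_split(np.arange(n_parcels), n_networks)
    centers = _lattice_points(n_networks) * _CENTER_SPACING
    centers = centers + rng.normal(scale=3.0, size=centers.shape)

    rows = []
    for k, block in enumerate(blocks):
        jitter = rng.normal(scale=_CENTROID_JITTER, size=(len(block), 3))
        coords = centers[k] + jitter
        for local, pid in enumerate(block):
            rows.append(
                {
                    "parcel_id": int(pid),
                    "parcel_name": f"{network_names[k]}_{local + 1}",
                    "network_label": network_names[k],
                    "x": coords[local, 0],
                    "y": coords[local, 1],
                    "z": coords[local, 2],
                }
            )
    return ParcelAtlas(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# covariance
# ---------------------------------------------------------------------------


def _nearest_correlation(c: np.ndarray) -> np.ndarray:
    """Project to the PSD cone by eigenvalue clipping, then re-normalize."""
    w, v = np.linalg.eigh(c)
    m = (v * np.clip(w, 0.0, None)) @ v.T
    d = np.sqrt(np.clip(np.diag(m), 1e-12, None))
    out = m / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2.0


def make_group_covariance(
    atlas: ParcelAtlas,
    within_r: float,
    between_r: float,
    offset: float = 0.0,
    planted_edges: Sequence[tuple] = (),
    planted_delta: float = 0.0,
) -> np.ndarray:
    """Block-modular correlation matrix with an optional planted edge set.

    Within-network entries are ``within_r + offset``, between-network
    entries ``between_r + offset``; planted edges receive an extra
    ``planted_delta``.  If the raw construction is not positive
    semidefinite it is projected to the nearest correlation matrix
    (eigenvalue clipping + re-normalization) and the repair is logged.
    """
    labels = atlas.network_labels
    n = atlas.n_parcels
    same = labels[:, None] == labels[None, :]
    c = np.where(same, within_r + offset, between_r + offset).astype(float)
    for i, j in planted_edges:
        if not (0 <= i < n and 0 <= j < n and i != j):
            raise ValueError(f"planted edge ({i}, {j}) out of range for N={n}")
        c[i, j] += planted_delta
        c[j, i] += planted_delta
    np.fill_diagonal(c, 1.0)
    if np.any(np.abs(c) > 1.0):
        logger.warning("covariance entries clipped into [-1, 1]")
        c = np.clip(c, -1.0, 1.0)
        np.fill_diagonal(c, 1.0)
    min_eig = float(np.linalg.eigvalsh(c)[0])
    if min_eig < -1e-10:
        logger.warning(
            "covariance not PSD (min eigenvalue %.3g); projecting to nearest "
            "correlation matrix",
            min_eig,
        )
        c = _nearest_correlation(c)
        min_eig = float(np.linalg.eigvalsh(c)[0])
        if min_eig < -1e-8:
            raise GenerationError(
                f"covariance still not PSD after projection (min eig {min_eig:.3g})"
            )
    return c


# ---------------------------------------------------------------------------
# subject simulation
# ---------------------------------------------------------------------------


def _psd_factor(cov: np.ndarray) -> np.ndarray:
    """Symmetric square-root factor of a PSD matrix (eigendecomposition)."""
    if np.isnan(cov).any():
        raise GenerationError("covariance contains NaN")
    w, v = np.linalg.eigh((cov + cov.T) / 2.0)
    if w[0] < -1e-8:
        raise GenerationError(f"covariance not PSD (min eigenvalue {w[0]:.3g})")
    return v * np.sqrt(np.clip(w, 0.0, None))


def _state_sequence(k: int, dwell: float, T: int, rng: np.random.Generator) -> np.ndarray:
    """Markov state path: switch with probability 1/dwell, uniform new state."""
    states = np.zeros(T, dtype=int)
    if k == 1:
        return states
    p_switch = 1.0 / float(dwell)
    s = int(rng.integers(k))
    switch = rng.random(T) < p_switch
    jumps = rng.integers(0, k - 1, size=T)
    for t in range(T):
        if t > 0 and switch[t]:
            s = (s + 1 + int(jumps[t])) % k
        states[t] = s
    return states


def simulate_subject(
    covariances: Sequence[np.ndarray],
    dwell: float,
    T: int,
    tr_seconds: float = 2.0,
    seed: int | np.random.Generator = 0,
    subject_id: str = "sub-0",
) -> ParcelTimeSeries:
    """Draw a T x N series from one or more covariance states.

    With a single covariance the series is stationary Gaussian; with
    several, the active state follows a geometric-dwell Markov chain
    (expected dwell ``dwell`` samples) and each sample is drawn from the
    active state's covariance.  Fully deterministic for a fixed seed.
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    if dwell < 1:
        raise ValueError("dwell must be >= 1 sample")
    covariances = [np.asarray(c, dtype=float) for c in covariances]
    if not covariances:
        raise ValueError("need at least one covariance state")
    n = covariances[0].shape[0]
    for c in covariances:
        if c.shape != (n, n):
            raise ValueError("all covariance states must share one shape")
    factors = [_psd_factor(c) for c in covariances]

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = _state_sequence(len(covariances), dwell, T, rng)
    z = rng.standard_normal((T, n))
    data = np.empty((T, n))
    for s, factor in enumerate(factors):
        mask = states == s
        if mask.any():
            data[mask] = z[mask] @ factor.T
    return ParcelTimeSeries(subject_id=subject_id, data=data, tr_seconds=tr_seconds)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def _planted_edges(atlas: ParcelAtlas, n_nodes: int) -> frozenset:
    """A connected planted component bridging two networks.

    Takes the first ``n_nodes // 2`` parcels of the second and third
    network blocks (somatomotor / dorsal-attention under the default
    labels) and plants every pair among the selected nodes — a clique,
    hence connected.  A uniform clique bump ``delta * (J - I)`` has
    minimum eigenvalue ``-delta``, so moderate deltas stay positive
    semidefinite without projection.
    """
    if n_nodes < 2:
        return frozenset()
    labels = atlas.network_labels
    names = list(dict.fromkeys(labels))
    if len(names) < 2:
        nodes = np.arange(min(n_nodes, atlas.n_parcels))
    else:
        net_a, net_b = names[1 % len(names)], names[2 % len(names)]
        if net_a == net_b:
            net_a, net_b = names[0], names[1]
        a = np.flatnonzero(labels == net_a)[: n_nodes // 2]
        b = np.flatnonzero(labels == net_b)[: (n_nodes + 1) // 2]
        nodes = np.concatenate([a, b])
    edges = {
        (int(min(i, j)), int(max(i, j)))
        for ii, i in enumerate(nodes)
        for j in nodes[ii + 1 :]
    }
    return frozenset(edges)


def _apply_planted(cov: np.ndarray, edges: frozenset, delta: float) -> np.ndarray:
    """Add a planted-edge bump to a correlation matrix, repairing PSD if needed."""
    c = cov.copy()
    for i, j in edges:
        c[i, j] += delta
        c[j, i] += delta
    c = np.clip(c, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    if float(np.linalg.eigvalsh(c)[0]) < -1e-10:
        logger.warning("planted bump broke PSD; projecting to nearest correlation")
        c = _nearest_correlation(c)
    return c


def _dwell_from_stability(s: float, dwell_range: tuple) -> float:
    lo, hi = dwell_range
    return float(np.exp(np.log(lo) + np.clip(s, 0.0, 1.0) * (np.log(hi) - np.log(lo))))


def generate_cohort(
    config: CohortConfig, seed: int = 0
) -> tuple[list, pd.DataFrame, CohortGroundTruth]:
    """Generate a full synthetic cohort.

    Returns ``(time_series_list, phenotypes, ground_truth)``.  Groups are
    age/sex/motion-matched by construction: demographic draws are made
    once per within-group index and copied across the matched tuple of
    subjects.  Each group has two covariance states — the block-modular
    group covariance and a parcel-permuted version of it — and subjects
    switch between them at a rate set by their stability parameter.
    """
    if len(config.groups) < 2:
        raise ValueError("config must name at least 2 groups")
    if config.n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")

    root = np.random.SeedSequence(seed)
    ss_atlas, ss_demo, ss_subjects, ss_scores, ss_perm = root.spawn(5)
    atlas = generate_atlas(
        config.n_parcels, config.n_networks, seed=np.random.default_rng(ss_atlas).integers(2**31)
    )

    any_delta = any(config.planted_delta.get(g, 0.0) != 0.0 for g in config.groups)
    planted = _planted_edges(atlas, config.n_planted_nodes) if any_delta else frozenset()

    # one fixed parcel permutation defines the alternative covariance state
    perm = np.random.default_rng(ss_perm).permutation(config.n_parcels)

    cov_params: dict = {}
    group_states: dict = {}
    for g in config.groups:
        offset = float(config.group_fc_offset.get(g, 0.0))
        delta = float(config.planted_delta.get(g, 0.0))
        base = make_group_covariance(
            atlas, config.within_r, config.between_r, offset
        )
        # alternative state: blend toward a parcel-permuted copy (still PSD,
        # same eigenvalue scale, different modular pattern)
        gamma = float(np.clip(config.state_contrast, 0.0, 1.0))
        alt = (1.0 - gamma) * base + gamma * base[np.ix_(perm, perm)]
        np.fill_diagonal(alt, 1.0)
        # the planted subnetwork is a trait effect: present in BOTH states
        if delta != 0.0 and planted:
            base = _apply_planted(base, planted, delta)
            alt = _apply_planted(alt, planted, delta)
        group_states[g] = (base, alt)
        cov_params[g] = {
            "within_r": config.within_r,
            "between_r": config.between_r,
            "global_offset": offset,
            "planted_delta": delta,
        }

    demo_rng = np.random.default_rng(ss_demo)
    ages = demo_rng.uniform(*config.age_range, size=config.n_per_group)
    sexes = np.where(demo_rng.random(config.n_per_group) < config.sex_p_female, "F", "M")
    fds = np.abs(demo_rng.normal(config.mean_fd_mean, config.mean_fd_sd, config.n_per_group))

    score_rng = np.random.default_rng(ss_scores)
    subject_seeds = ss_subjects.spawn(len(config.groups) * config.n_per_group)

    series: list[ParcelTimeSeries] = []
    rows = []
    stability: dict = {}
    idx = 0
    for g in config.groups:
        mu = float(config.stability_mean.get(g, 0.5))
        for i in range(config.n_per_group):
            sid = f"{g}{i:03d}"
            s_param = float(np.clip(score_rng.normal(mu, config.stability_sd), 0.0, 1.0))
            dwell = _dwell_from_stability(s_param, config.dwell_range)
            ts = simulate_subject(
                group_states[g],
                dwell=dwell,
                T=config.n_timepoints,
                tr_seconds=config.tr_seconds,
                seed=np.random.default_rng(subject_seeds[idx]),
                subject_id=sid,
            )
            series.append(ts)
            stability[sid] = s_param
            row = {
                "subject_id": sid,
                "group": g,
                "age": float(ages[i]),
                "sex": str(sexes[i]),
                "mean_fd": float(fds[i]),
            }
            for name, (inter, slope, sd) in config.score_loadings.items():
                row[name] = float(inter + slope * s_param + score_rng.normal(0.0, sd))
            if g == config.groups[-1]:
                row["disease_duration"] = float(score_rng.uniform(1.0, 20.0))
            rows.append(row)
            idx += 1

    phenotypes = pd.DataFrame(rows)
    truth = CohortGroundTruth(
        planted_component_edges=planted,
        group_covariance_params=cov_params,
        stability_param=stability,
        score_loadings={k: tuple(v) for k, v in config.score_loadings.items()},
    )
    return series, phenotypes, truth


def cohort_atlas(config: CohortConfig, seed: int = 0) -> ParcelAtlas:
    """The atlas a ``generate_cohort`` call with the same seed would use."""
    ss_atlas = np.random.SeedSequence(seed).spawn(5)[0]
    return generate_atlas(
        config.n_parcels, config.n_networks, seed=np.random.default_rng(ss_atlas).integers(2**31)
    )


# ---------------------------------------------------------------------------
# file I/O (plain TSV / JSON)
# ---------------------------------------------------------------------------


def write_atlas_tsv(atlas: ParcelAtlas, path: str | Path) -> None:
    atlas.table.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_atlas_tsv(path: str | Path) -> ParcelAtlas:
    return ParcelAtlas(pd.read_csv(path, sep="\t"))


def write_timeseries_tsv(ts: ParcelTimeSeries, path: str | Path) -> None:
    """Rows = timepoints, columns = parcel ids; TR stored on a comment line."""
    with open(path, "w") as fh:
        fh.write(f"# subject_id={ts.subject_id} tr_seconds={ts.tr_seconds}\n")
        header = "\t".join(f"p{j}" for j in range(ts.n_parcels))
        fh.write(header + "\n")
        np.savetxt(fh, ts.data, delimiter="\t", fmt="%.8g")


def read_timeseries_tsv(path: str | Path) -> ParcelTimeSeries:
    path = Path(path)
    subject_id, tr = path.stem, 2.0
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first[1:].split():
            key, _, val = tok.partition("=")
            if key == "subject_id":
                subject_id = val
            elif key == "tr_seconds":
                tr = float(val)
    data = pd.read_csv(path, sep="\t", comment="#").to_numpy(dtype=float)
    return ParcelTimeSeries(subject_id=subject_id, data=data, tr_seconds=tr)


def write_phenotypes_tsv(phenotypes: pd.DataFrame, path: str | Path) -> None:
    phenotypes.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_phenotypes_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ground_truth_json(truth: CohortGroundTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1)


def config_to_dict(config: CohortConfig) -> dict:
    out = dataclasses.asdict(config)
    for key, value in out.items():
        if isinstance(value, tuple):
            out[key] = list(value)
    return out
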