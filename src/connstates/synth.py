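"""Synthetic paired-cohort generator for brain-state classification studies.

The generator emulates the post-preprocessing form the feature pipeline
consumes: z-scored parcel time courses with a shared global component,
network-structured block covariance, and state-dependent perturbations.

Model
-----
A parcel ``p`` in network ``n`` follows a linear factor model::

    x_p(t) = global_amp * g(t) + net_amp[n] * u_n(t) + noise_sd * eps_p(t)

with ``g``, ``eps_p`` i.i.d. standard normal, and the 7 network factors
``u`` jointly standard normal with correlation matrix ``coupling``.
Columns are z-scored afterwards, so only correlations matter downstream.
The model-implied parcel correlation is available in closed form
(:func:`implied_correlation`), which makes recovery tests exact up to
sampling error.

A condition is a pair of :class:`StateParams` (baseline vs. atypical);
each subject receives one scan per state, with subject-level multiplicative
log-normal jitter on the amplitudes shared between the two scans (stable
subject traits survive the paired contrast, state effects do not).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .partition import NETWORKS, NetworkPartition
from .timeseries import ParcelTimeSeries, standardize_columns

#: Multiplicative log-normal sigma of the per-subject amplitude jitter.
SUBJECT_JITTER_SIGMA = 0.1


class ModelError(ValueError):
    """The state parameters do not define a valid (PSD) covariance."""


# --------------------------------------------------------------------------- #
# State parameters
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class StateParams:
    """Generator parameters for one brain state.

    Parameters
    ----------
    global_amp
        Weight of the shared global signal (>= 0).
    net_amp
        Within-network factor weight per network (>= 0).
    coupling
        7 x 7 inter-network factor correlation matrix, aligned with
        ``networks``; symmetric, unit diagonal, entries in [-1, 1], PSD.
    noise_sd
        Standard deviation of i.i.d. parcel noise (> 0 in practice; 0 is
        allowed but then every parcel must still have positive variance).
    perturbation_tags
        Named planted effects, e.g. ``("coupling", "VIS", "SMN")`` — pure
        bookkeeping consumed by :func:`planted_effects`.
    """

    global_amp: float
    net_amp: Mapping[str, float]
    coupling: np.ndarray
    noise_sd: float
    networks: tuple[str, ...] = NETWORKS
    perturbation_tags: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self) -> None:
        K = len(self.networks)
        cpl = np.asarray(self.coupling, dtype=float)
        if cpl.shape != (K, K):
            raise ModelError(f"coupling must be {K}x{K}, got {cpl.shape}")
        if not np.allclose(cpl, cpl.T, atol=1e-12):
            raise ModelError("coupling must be symmetric")
        if not np.allclose(np.diag(cpl), 1.0, atol=1e-12):
            raise ModelError("coupling must have unit diagonal")
        if np.abs(cpl).max() > 1 + 1e-12:
            raise ModelError("coupling entries must lie in [-1, 1]")
        if np.linalg.eigvalsh(cpl).min() < -1e-10:
            raise ModelError("coupling matrix is not positive semidefinite")
        if self.global_amp < 0:
            raise ModelError("global_amp must be nonnegative")
        if self.noise_sd < 0:
            raise ModelError("noise_sd must be nonnegative")
        missing = set(self.networks) - set(self.net_amp)
        if missing:
            raise ModelError(f"net_amp missing networks: {sorted(missing)}")
        if any(self.net_amp[n] < 0 for n in self.networks):
            raise ModelError("net_amp values must be nonnegative")
        object.__setattr__(self, "coupling", cpl)
        object.__setattr__(self, "net_amp", dict(self.net_amp))
        object.__setattr__(self, "perturbation_tags", tuple(tuple(t) for t in self.perturbation_tags))

    # -- constructors -------------------------------------------------------

    @classmethod
    def uniform(
        cls,
        global_amp: float = 0.5,
        net_amp: float = 0.8,
        coupling_offdiag: float = 0.3,
        noise_sd: float = 1.0,
        networks: Sequence[str] = NETWORKS,
    ) -> "StateParams":
        """Exchangeable parameters: same amplitude and coupling everywhere."""
        networks = tuple(networks)
        K = len(networks)
        cpl = np.full((K, K), coupling_offdiag, dtype=float)
        np.fill_diagonal(cpl, 1.0)
        return cls(
            global_amp=global_amp,
            net_amp={n: net_amp for n in networks},
            coupling=cpl,
            noise_sd=noise_sd,
            networks=networks,
        )

    # -- perturbations ------------------------------------------------------

    def with_coupling(self, a: str, b: str, value: float) -> "StateParams":
        """Copy with the (a, b) inter-network coupling set to ``value``."""
        ia, ib = self.networks.index(a), self.networks.index(b)
        cpl = self.coupling.copy()
        cpl[ia, ib] = cpl[ib, ia] = value
        tag = ("coupling", *sorted((a, b), key=self.networks.index))
        return replace(self, coupling=cpl, perturbation_tags=self.perturbation_tags + (tag,))

    def with_global_amp(self, value: float) -> "StateParams":
        return replace(
            self, global_amp=value, perturbation_tags=self.perturbation_tags + (("global_amp",),)
        )

    def with_net_amp(self, network: str, value: float) -> "StateParams":
        if network not in self.networks:
            raise ModelError(f"unknown network {network!r}")
        amp = dict(self.net_amp)
        amp[network] = value
        return replace(
            self, net_amp=amp, perturbation_tags=self.perturbation_tags + (("net_amp", network),)
        )

    def _jittered(self, m_global: float, m_net: np.ndarray) -> "StateParams":
        amp = {n: self.net_amp[n] * m_net[k] for k, n in enumerate(self.networks)}
        return replace(self, global_amp=self.global_amp * m_global, net_amp=amp)


# --------------------------------------------------------------------------- #
# Closed-form implied correlation
# --------------------------------------------------------------------------- #


def implied_correlation(params: StateParams, partition: NetworkPartition) -> np.ndarray:
    """Model-implied parcel correlation matrix (exact, closed form).

    cov(p, q) = global_amp^2 + a_p a_q K[n_p, n_q] + [p == q] noise_sd^2
    with ``a_p = net_amp[network(p)]``; correlations follow by scaling.
    """
    codes = partition.label_codes()
    amps = np.array([params.net_amp[lab] for lab in partition.labels])
    cov = params.global_amp**2 + np.outer(amps, amps) * params.coupling[np.ix_(codes, codes)]
    var = np.diag(cov).copy() + params.noise_sd**2
    if var.min() < 1e-12:
        raise ModelError("a parcel has zero implied variance")
    cov = cov.copy()
    np.fill_diagonal(cov, var)
    d = 1.0 / np.sqrt(var)
    return cov * np.outer(d, d)


# --------------------------------------------------------------------------- #
# Simulation
# --------------------------------------------------------------------------- #


def simulate_scan(
    params: StateParams,
    partition: NetworkPartition,
    t_points: int,
    seed: int,
    *,
    subject_id: str = "sub000",
    state: str = "baseline",
    condition: str = "synthetic",
) -> ParcelTimeSeries:
    """Draw one scan from the factor model and z-score each parcel.

    Reproducible: identical arguments yield bit-identical output.
    """
    if params.networks != partition.networks:
        raise ModelError("params and partition declare different networks")
    rng = np.random.default_rng(seed)
    K = len(params.networks)
    codes = partition.label_codes()
    amps = np.array([params.net_amp[lab] for lab in partition.labels])

    # PSD square root of the coupling (tolerates semidefinite matrices).
    w, V = np.linalg.eigh(params.coupling)
    if w.min() < -1e-10:
        raise ModelError("coupling matrix is not positive semidefinite")
    A = V * np.sqrt(np.clip(w, 0.0, None))

    g = rng.standard_normal(t_points)
    U = rng.standard_normal((t_points, K)) @ A.T
    eps = rng.standard_normal((t_points, partition.parcel_count))

    X = params.global_amp * g[:, None] + amps[None, :] * U[:, codes] + params.noise_sd * eps
    X = standardize_columns(X)
    return ParcelTimeSeries(
        data=X, subject_id=subject_id, state=state, condition=condition, variant="noGSR"
    )


@dataclass(frozen=True)
class CohortDataset:
    """Paired cohort: one baseline and one atypical scan per subject."""

    scans: tuple[ParcelTimeSeries, ...]
    partition: NetworkPartition
    pairing: Mapping[str, tuple[int, int]]  # subject -> (baseline idx, atypical idx)
    condition: str
    seed: int
    baseline_params: StateParams | None = None
    atypical_params: StateParams | None = None

    def __post_init__(self) -> None:
        for sub, (ib, ia) in self.pairing.items():
            if self.scans[ib].state != "baseline" or self.scans[ia].state != "atypical":
                raise ValueError(f"pairing for subject {sub!r} mislabels states")
            if self.scans[ib].subject_id != sub or self.scans[ia].subject_id != sub:
                raise ValueError(f"pairing for subject {sub!r} references other subjects")
        states = [s.state for s in self.scans]
        if states.count("baseline") != states.count("atypical"):
            raise ValueError("cohort must be state-balanced")

    @property
    def subjects(self) -> list[str]:
        return list(self.pairing)

    @property
    def n_subjects(self) -> int:
        return len(self.pairing)

    def labels(self) -> np.ndarray:
        """0 = baseline, 1 = atypical, in scan order."""
        return np.array([1 if s.state == "atypical" else 0 for s in self.scans])

    def subject_ids(self) -> np.ndarray:
        return np.array([s.subject_id for s in self.scans])

    def scan_ids(self) -> list[str]:
        return [s.scan_id for s in self.scans]


def simulate_condition(
    baseline: StateParams,
    atypical: StateParams,
    partition: NetworkPartition,
    n_subjects: int,
    t_points: int,
    seed: int,
    *,
    condition: str = "synthetic",
) -> CohortDataset:
    """Simulate a paired cohort of ``n_subjects`` (two scans each).

    Per-subject amplitude jitter (log-normal, sigma 0.1) is drawn once per
    subject and applied to both states, so it cancels in the within-subject
    contrast but adds realistic between-subject spread.
    """
    if n_subjects < 4:
        raise ValueError("need at least 4 subjects to form 3 inner CV folds")
    rng = np.random.default_rng(seed)
    K = len(partition.networks)
    scans: list[ParcelTimeSeries] = []
    pairing: dict[str, tuple[int, int]] = {}
    for i in range(n_subjects):
        sub = f"sub{i:03d}"
        m_global = rng.lognormal(mean=0.0, sigma=SUBJECT_JITTER_SIGMA)
        m_net = rng.lognormal(mean=0.0, sigma=SUBJECT_JITTER_SIGMA, size=K)
        seed_b, seed_a = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
        scan_b = simulate_scan(
            baseline._jittered(m_global, m_net), partition, t_points, seed_b,
            subject_id=sub, state="baseline", condition=condition,
        )
        scan_a = simulate_scan(
            atypical._jittered(m_global, m_net), partition, t_points, seed_a,
            subject_id=sub, state="atypical", condition=condition,
        )
        pairing[sub] = (len(scans), len(scans) + 1)
        scans.extend([scan_b, scan_a])
    return CohortDataset(
        scans=tuple(scans),
        partition=partition,
        pairing=pairing,
        condition=condition,
        seed=seed,
        baseline_params=baseline,
        atypical_params=atypical,
    )


# --------------------------------------------------------------------------- #
# Planted-effect bookkeeping
# --------------------------------------------------------------------------- #


def planted_effects(
    tags: Sequence[Sequence[str]],
    partition: NetworkPartition,
) -> list[str]:
    """Canonical feature names expected to discriminate for planted effects.

    Supported tags: ``("coupling", A, B)``, ``("global_amp",)``,
    ``("net_amp", N)``.  Unknown tags raise ``ValueError``.
    """
    names: list[str] = []
    for tag in tags:
        tag = tuple(tag)
        if tag[0] == "coupling" and len(tag) == 3:
            pair = partition.pair_name(tag[1], tag[2])
            names += [f"conn_noGSR:mean:{pair}", f"conn_GSR:mean:{pair}"]
        elif tag[0] == "global_amp" and len(tag) == 1:
            # GSR removes the global component, so only the noGSR mean responds.
            names += ["conn_noGSR:mean:whole"]
        elif tag[0] == "net_amp" and len(tag) == 2:
            if tag[1] not in partition.networks:
                raise ValueError(f"unknown network in tag {tag!r}")
            names += [f"conn_noGSR:mean:{tag[1]}", f"conn_GSR:mean:{tag[1]}"]
        else:
            raise ValueError(f"unknown perturbation tag {tag!r}")
    # stable de-duplication
    seen: set[str] = set()
    out = []
    for n in names:
        if n not in seen:
            seen.add(n)
            out.append(n)
    return out


def condition_effects(baseline: StateParams, atypical: StateParams,
                      partition: NetworkPartition) -> list[str]:
    """Planted feature names for a condition, from the atypical state's tags."""
    tags = [t for t in atypical.perturbation_tags if t not in baseline.perturbation_tags]
    return planted_effects(tags, partition)
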