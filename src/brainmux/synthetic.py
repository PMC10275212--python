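"""Synthetic multimodal cohort generation.

Generates cohorts with the statistical structure the downstream analysis
assumes, so every stage is testable without any acquisition data:

* six MEG-like band layers — noisy phase-lagged Kuramoto oscillators with a
  carrier inside each canonical band, strong within-module coupling, weak
  between-module coupling, and fronto-parietal (FPN) to other-module
  coupling scaled monotonically by a subject-level latent integration
  factor; a fixed nonzero phase lag keeps the PLI bounded away from 0 for
  coupled pairs;
* one BOLD-like layer — module factor model time series whose FPN regions
  load on a global factor with a weight increasing in the latent factor;
* one structural layer — heavy-tailed (log-normal) nonnegative streamline-
  count-like weights with hub propensities and module co-membership
  structure, FPN-to-other weights scaled by the latent factor;
* covariates — age uniform over the age range, a quadratic age trend in the
  latent integration factor, and an executive-functioning (EF) composite
  coupled to the standardized latent factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .atlas import SEVEN_NETWORKS, AtlasMapping, make_atlas
from .connectivity import CANONICAL_BANDS, MEG_BAND_NAMES, BandSpec, ConnectivityMatrix, EpochedTimeSeries

__all__ = [
    "CohortParams",
    "ModuleCoupling",
    "SyntheticSubject",
    "SyntheticCohort",
    "LAYER_ORDER",
    "generate_cohort",
    "generate_band_series",
    "generate_structural_matrix",
    "params_197",
]

#: Fixed layer order used throughout the pipeline.
LAYER_ORDER: tuple[str, ...] = MEG_BAND_NAMES + ("rsfmri", "dmri")

#: Components whose mean defines the EF composite.
EF_COMPONENTS: tuple[str, ...] = ("word_fluency", "stroop_interference", "cst_shift")


@dataclass(frozen=True)
class ModuleCoupling:
    """Oscillator coupling configuration for the MEG-like band layers.

    Units: coupling gains and phase-noise sd are in rad/s; ``phase_lag`` in
    radians (fixed nonzero so coupled pairs show a consistent lag and the
    PLI does not vanish); ``fpn_gain`` is the exponential sensitivity of the
    FPN-to-other coupling to the standardized latent integration factor.
    """

    k_within: float = 12.0
    k_between: float = 0.1
    k_fpn_base: float = 1.5
    fpn_gain: float = 0.5
    phase_lag: float = 0.8
    phase_noise_sd: float = 1.2
    freq_jitter_frac: float = 0.06  # per-node carrier jitter sd / bandwidth

    def coupling_matrix(self, atlas: AtlasMapping, latent_z: float) -> np.ndarray:
        """Directed N x N coupling gains; K[i, j] is the pull of j on i.

        Coupling is leader-follower so locked pairs settle at the imposed
        nonzero lag (a symmetric lagged coupling is frustrated and locks at
        zero lag, which the PLI cannot see): within a module the
        higher-index node follows the lower-index one, FPN-to-other pairs
        have the non-FPN node follow the FPN node (with gain scaled by the
        latent integration factor), and remaining between-module pairs
        follow the lower index weakly.
        """
        nets = np.asarray(atlas.subnetworks)
        n = nets.size
        same = nets[:, None] == nets[None, :]
        fpn = nets == "FPN"
        cross_fpn = (fpn[:, None] ^ fpn[None, :]) & ~same
        idx = np.arange(n)
        follows = idx[:, None] > idx[None, :]  # receiver i, driver j < i
        k = np.zeros((n, n))
        k[same & follows] = self.k_within
        k[~same & ~cross_fpn & follows] = self.k_between
        k_fpn = self.k_fpn_base * float(np.exp(self.fpn_gain * latent_z))
        receiver_not_fpn = ~fpn[:, None] & fpn[None, :]
        k[cross_fpn & receiver_not_fpn] = k_fpn
        np.fill_diagonal(k, 0.0)
        return k


@dataclass(frozen=True)
class CohortParams:
    """Study conditions for one synthetic cohort."""

    n_subjects: int = 33
    n_regions: int = 60
    subnetwork_sizes: Mapping[str, int] | None = None
    age_range: tuple[float, float] = (20.0, 70.0)
    age_quad_coeffs: tuple[float, float, float] = (-2.0, 0.16, -0.0018)
    effect_slope: float = 0.6
    noise_sd: float = 0.5
    sampling_rate: float = 1250.0
    n_epochs: int = 88
    epoch_len: int = 4096
    n_bold_samples: int = 310
    coupling: ModuleCoupling = field(default_factory=ModuleCoupling)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.n_regions < 10:
            raise ValueError(
                f"n_regions={self.n_regions} too small for a 7-module partition"
            )
        sizes = dict(self.subnetwork_sizes) if self.subnetwork_sizes else None
        if sizes is not None:
            if set(sizes) != set(SEVEN_NETWORKS):
                raise ValueError(
                    f"subnetwork sizes must cover exactly {sorted(SEVEN_NETWORKS)}"
                )
            if sum(sizes.values()) != self.n_regions:
                raise ValueError("subnetwork sizes do not partition n_regions")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range lower bound must be below upper bound")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.sampling_rate <= 0 or self.n_epochs < 1 or self.epoch_len < 2:
            raise ValueError("invalid sampling/epoch configuration")

    def atlas(self) -> AtlasMapping:
        sizes = dict(self.subnetwork_sizes) if self.subnetwork_sizes else None
        return make_atlas(self.n_regions, sizes)


def params_197(**overrides) -> CohortParams:
    """Preset mirroring the post-exclusion 197-region parcel count."""
    return CohortParams(n_regions=197, **overrides)


@dataclass
class SyntheticSubject:
    subject_id: str
    age: float
    sex: str
    education: int
    latent_g: float
    latent_z: float
    cognition: dict[str, float]
    layers: dict[str, EpochedTimeSeries | ConnectivityMatrix] = field(default_factory=dict)


@dataclass
class SyntheticCohort:
    params: CohortParams
    atlas: AtlasMapping
    subjects: list[SyntheticSubject]

    def covariates(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {
                "subject_id": s.subject_id,
                "age": s.age,
                "sex": s.sex,
                "education": s.education,
                "latent_g": s.latent_g,
                "latent_z": s.latent_z,
            }
            row.update(s.cognition)
            rows.append(row)
        return pd.DataFrame(rows).set_index("subject_id")


def _module_carriers(band: BandSpec, atlas: AtlasMapping) -> np.ndarray:
    """Per-region carrier frequency: one carrier per module, spread in-band.

    Modules occupy evenly spaced carriers over the central 80% of the band,
    so within-module pairs have (near) zero detuning and can phase-lock
    under weak coupling while between-module pairs beat several times per
    epoch, keeping the uncoupled PLI baseline low.
    """
    labels = list(dict.fromkeys(atlas.subnetworks))
    bw = band.f_hi - band.f_lo
    lo = band.f_lo + 0.1 * bw
    step = 0.8 * bw / max(1, len(labels) - 1) if len(labels) > 1 else 0.0
    per_module = {lab: lo + k * step for k, lab in enumerate(labels)}
    return np.asarray([per_module[s] for s in atlas.subnetworks])


def generate_band_series(
    subject: SyntheticSubject,
    band: str | BandSpec,
    module_coupling: ModuleCoupling,
    seed: int,
    *,
    atlas: AtlasMapping,
    sampling_rate: float = 1250.0,
    n_epochs: int = 88,
    epoch_len: int = 4096,
) -> EpochedTimeSeries:
    """Phase-coupled noisy oscillator series for one subject and band.

    Euler-integrated Kuramoto dynamics with a fixed phase lag between coupled
    pairs; each region's carrier frequency sits inside the requested band
    (mid-band plus a small jitter), so the spectral peak lies in-band.
    """
    if isinstance(band, str):
        if band not in CANONICAL_BANDS:
            raise ValueError(
                f"unknown band {band!r}; expected one of {list(CANONICAL_BANDS)}"
            )
        band = CANONICAL_BANDS[band]
    n = len(atlas)
    rng = np.random.default_rng(seed)
    k = module_coupling.coupling_matrix(atlas, subject.latent_z)
    # scale so effective pairwise pull is size-independent (tuned at N=28)
    k = k * 28.0 / max(28, n)
    carriers = _module_carriers(band, atlas)
    jitter = module_coupling.freq_jitter_frac * (band.f_hi - band.f_lo)
    freqs = carriers + rng.normal(0.0, jitter, size=n)
    omega = 2.0 * np.pi * freqs
    dt = 1.0 / sampling_rate
    burn = min(200, epoch_len)
    total = n_epochs * epoch_len + burn
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    # coupling term: Im(e^{-i phi_i} sum_j K_ij e^{-i alpha} e^{i phi_j})
    kc = k * np.exp(-1j * module_coupling.phase_lag)
    noise_scale = module_coupling.phase_noise_sd * np.sqrt(dt)
    out = np.empty((total, n))
    for t in range(total):
        z = np.exp(1j * phi)
        drive = np.imag(np.conj(z) * (kc @ z))
        phi = phi + dt * (omega + drive) + noise_scale * rng.standard_normal(n)
        out[t] = np.sin(phi)
    values = out[burn:].reshape(n_epochs, epoch_len, n)
    return EpochedTimeSeries(values, sampling_rate, atlas.region_names)


def _generate_bold_series(
    subject_latent_z: float,
    atlas: AtlasMapping,
    rng: np.random.Generator,
    n_samples: int,
    sampling_rate: float = 1.0 / 1.52,
) -> EpochedTimeSeries:
    """Module factor-model BOLD-like series (single continuous epoch)."""
    n = len(atlas)
    nets = np.asarray(atlas.subnetworks)
    labels = list(dict.fromkeys(nets))
    factors = rng.standard_normal((n_samples, len(labels)))
    glob = rng.standard_normal(n_samples)
    noise = rng.standard_normal((n_samples, n))
    # FPN regions load more on the global factor as integration increases
    g_fpn = 0.35 + 0.25 * np.tanh(subject_latent_z)
    data = np.empty((n_samples, n))
    for r in range(n):
        mod = labels.index(nets[r])
        g = g_fpn if nets[r] == "FPN" else 0.25
        lam_mod = 0.6
        resid = np.sqrt(max(1e-6, 1.0 - lam_mod**2 - g**2))
        data[:, r] = lam_mod * factors[:, mod] + g * glob + resid * noise[:, r]
    return EpochedTimeSeries(data[None, :, :], sampling_rate, atlas.region_names)


def generate_structural_matrix(
    subject: SyntheticSubject | float,
    params: CohortParams,
    seed: int,
    *,
    atlas: AtlasMapping | None = None,
) -> ConnectivityMatrix:
    """Heavy-tailed streamline-count-like structural matrix.

    ``w_ij = eta_i * eta_j * m_ij * eps_ij`` with log-normal hub propensities
    ``eta``, a module co-membership factor ``m`` (within > between, FPN-to-
    other scaled by the latent factor), and log-normal noise ``eps``. The
    matrix is symmetric, zero-diagonal, nonnegative and connected (all
    off-diagonal weights positive).
    """
    latent_z = subject.latent_z if isinstance(subject, SyntheticSubject) else float(subject)
    atlas = atlas or params.atlas()
    n = len(atlas)
    rng = np.random.default_rng(seed)
    eta = rng.lognormal(0.0, 0.6, size=n)
    nets = np.asarray(atlas.subnetworks)
    same = nets[:, None] == nets[None, :]
    fpn = nets == "FPN"
    cross_fpn = (fpn[:, None] ^ fpn[None, :]) & ~same
    m = np.where(same, 3.0, 1.0)
    m = np.where(cross_fpn, np.exp(0.5 * latent_z), m)
    eps = rng.lognormal(0.0, 2.0, size=(n, n))
    eps = np.triu(eps, 1)
    eps = eps + eps.T
    w = eta[:, None] * eta[None, :] * m * eps * 100.0
    np.fill_diagonal(w, 0.0)
    sid = subject.subject_id if isinstance(subject, SyntheticSubject) else ""
    return ConnectivityMatrix(w, modality="dmri", subject_id=sid,
                              region_labels=atlas.region_names)


def generate_exchangeable_correlation_matrix(
    atlas: AtlasMapping,
    seed: int,
    n_samples: int = 310,
) -> ConnectivityMatrix:
    """Absolutized-correlation weight multiset with no positional signal.

    Builds the |Pearson r| matrix of modular Gaussian time series, then
    reassigns its off-diagonal weights uniformly among the region pairs.
    The result is statistically exchangeable with weight-permutation null
    ensembles, which makes it the reference input for calibration studies
    of the edge-significance procedure.
    """
    from .connectivity import correlation_matrix  # local: avoid cycle at import

    n = len(atlas)
    rng = np.random.default_rng(seed)
    nets = np.asarray(atlas.subnetworks)
    labels = list(dict.fromkeys(nets))
    factors = rng.standard_normal((n_samples, len(labels)))
    data = np.empty((n_samples, n))
    for r in range(n):
        data[:, r] = (0.6 * factors[:, labels.index(nets[r])]
                      + 0.8 * rng.standard_normal(n_samples))
    w = correlation_matrix(data).weights
    iu = np.triu_indices(n, 1)
    shuffled = rng.permutation(w[iu])
    out = np.zeros_like(w)
    out[iu] = shuffled
    out += out.T
    return ConnectivityMatrix(out, modality="rsfmri_null",
                              region_labels=atlas.region_names)


def generate_cohort(params: CohortParams, with_layers: bool = True) -> SyntheticCohort:
    """Generate a full multimodal cohort (deterministic in ``params.seed``).

    Latent integration: ``g = a0 + a1*age + a2*age^2 + N(0, noise_sd)``;
    executive functioning: ``EF = effect_slope * z(g) + N(0, noise_sd)``,
    with three component test z-scores whose mean is exactly the EF value.
    ``with_layers=False`` skips layer generation (covariates only), for
    statistical studies that do not need the imaging layers.
    """
    atlas = params.atlas()
    ss = np.random.SeedSequence(params.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    n = params.n_subjects
    a0, a1, a2 = params.age_quad_coeffs
    ages = rng.uniform(*params.age_range, size=n)
    latent = a0 + a1 * ages + a2 * ages**2 + rng.normal(0.0, params.noise_sd, size=n)
    sd = latent.std(ddof=0)
    latent_z = (latent - latent.mean()) / sd if sd > 0 else np.zeros(n)
    ef = params.effect_slope * latent_z + rng.normal(0.0, params.noise_sd, size=n)
    sexes = rng.choice(["F", "M"], size=n)
    education = rng.integers(4, 8, size=n)

    subjects: list[SyntheticSubject] = []
    layer_seeds = ss.spawn(n)
    for i in range(n):
        # component z-scores centred so their mean is exactly the EF value
        delta = rng.normal(0.0, 0.2, size=len(EF_COMPONENTS))
        delta -= delta.mean()
        cognition = {c: float(ef[i] + d) for c, d in zip(EF_COMPONENTS, delta)}
        cognition["EF"] = float(ef[i])
        subj = SyntheticSubject(
            subject_id=f"sub-{i:03d}",
            age=float(ages[i]),
            sex=str(sexes[i]),
            education=int(education[i]),
            latent_g=float(latent[i]),
            latent_z=float(latent_z[i]),
            cognition=cognition,
        )
        if with_layers:
            child = np.random.default_rng(layer_seeds[i])
            band_seeds = child.integers(0, 2**31 - 1, size=len(MEG_BAND_NAMES) + 2)
            for k, bname in enumerate(MEG_BAND_NAMES):
                subj.layers[bname] = generate_band_series(
                    subj, bname, params.coupling, int(band_seeds[k]),
                    atlas=atlas,
                    sampling_rate=params.sampling_rate,
                    n_epochs=params.n_epochs,
                    epoch_len=params.epoch_len,
                )
            subj.layers["rsfmri"] = _generate_bold_series(
                subj.latent_z, atlas,
                np.random.default_rng(int(band_seeds[-2])),
                params.n_bold_samples,
            )
            subj.layers["dmri"] = generate_structural_matrix(
                subj, params, int(band_seeds[-1]), atlas=atlas
            )
        subjects.append(subj)
    return SyntheticCohort(params, atlas, subjects)
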