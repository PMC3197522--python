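"""Synthetic BOLD-like cohorts with controllable network topology and spectra.

This module generates the inputs the rest of the package analyses: a 3-D
label atlas of six resting-state networks (RSNs) — three "cognitive"
(CEN, DAN, DMN), three "perceptual" (SMN, AN, VN) — and, per subject, a 4-D
voxel time-series volume plus the nuisance regressors (motion, white-matter,
ventricular and global signals) that a resting-state preprocessing stream
expects to remove.

The generative model is deliberately simple and fully documented in
``docs/methods.md``:

* Each network occupies a compact blob of voxels on the grid; adjacent
  blobs share a configurable fraction of voxels (multi-label overlap).
* Within a network, ``n_communities`` community latents drive the voxels.
  A voxel's clean signal is a distance-weighted mixture of the community
  latents (Gaussian kernel on the distance to each community centre), so
  voxels near a community centre are near-copies of its latent while
  boundary voxels blend two communities and act as topological bridges.
* Community latents share a network latent at ``between_community_r`` and
  all network latents share (with opposite signs for the two groups) a weak
  cohort latent, which induces the cognitive-vs-perceptual anti-correlation
  seen in resting data.
* Every latent is spectrally shaped in the frequency domain so that the
  fraction of its power inside the low-frequency band (0.01–0.08 Hz)
  equals ``low_freq_fraction`` exactly.
* Observed voxel signal = ``g``·clean + ``noise_sd``·white noise, with the
  mixing weight ``g`` solved from ``within_community_r`` so that two voxels
  of the same community correlate at the target value; nuisance sources are
  added on top with per-voxel random loadings.

Everything is deterministic given ``GeneratorConfig.seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from numpy.fft import irfft, rfftfreq

__all__ = [
    "NetworkSpec",
    "GeneratorConfig",
    "RSNAtlas",
    "BoldDataset",
    "default_networks",
    "generate_atlas",
    "generate_cohort",
    "retained_volumes",
    "ACQUIRED_VOLUMES",
    "DUMMY_VOLUMES",
]

COGNITIVE = "cognitive"
PERCEPTUAL = "perceptual"

#: Volumes acquired per run and dummy volumes discarded for T1 saturation;
#: their difference is the default number of retained time points.
ACQUIRED_VOLUMES = 255
DUMMY_VOLUMES = 5

#: Default low-frequency band of interest (Hz).
DEFAULT_BAND = (0.01, 0.08)

#: Fraction of the shared cohort latent in each network latent (squared
#: loading); signs differ between groups, producing mild anti-correlation
#: between cognitive and perceptual network time-courses.
CROSS_GROUP_COUPLING = 0.15

#: Width of the community-weight kernel, as a multiple of the median
#: voxel-to-nearest-centre distance within a network.  Narrow enough that
#: communities stay distinct, wide enough that boundary voxels bridge them.
KERNEL_WIDTH_SCALE = 0.45


class GeneratorError(ValueError):
    """Raised for invalid or unsatisfiable generator configurations."""


@dataclass(frozen=True)
class NetworkSpec:
    """Target statistics for one synthetic resting-state network.

    Parameters
    ----------
    name:
        Network label (e.g. ``"DMN"``).
    group:
        ``"cognitive"`` or ``"perceptual"``.
    n_voxels:
        Number of voxels the network occupies on the grid.
    n_communities:
        Number of community latents driving the network's voxels. More
        communities with a low ``between_community_r`` yield a modular,
        sparser correlation graph (higher normalised clustering); few
        communities with high coupling yield a dense, near-random graph.
    within_community_r:
        Target Pearson correlation between two voxels of the same
        community, in (0, 1).
    between_community_r:
        Target correlation between the community latents themselves, in
        [0, within_community_r).
    low_freq_fraction:
        Fraction of the clean signal's spectral power inside the
        0.01–0.08 Hz band, in (0, 1).
    """

    name: str
    group: str
    n_voxels: int
    n_communities: int
    within_community_r: float
    between_community_r: float
    low_freq_fraction: float

    def validate(self) -> None:
        if self.group not in (COGNITIVE, PERCEPTUAL):
            raise GeneratorError(
                f"network {self.name!r}: group must be "
                f"'{COGNITIVE}' or '{PERCEPTUAL}', got {self.group!r}"
            )
        if self.n_voxels < 1:
            raise GeneratorError(f"network {self.name!r}: n_voxels must be ≥ 1")
        if self.n_communities < 1:
            raise GeneratorError(f"network {self.name!r}: n_communities must be ≥ 1")
        if not 0.0 < self.within_community_r < 1.0:
            raise GeneratorError(
                f"network {self.name!r}: within_community_r must lie in (0, 1); "
                f"got {self.within_community_r} (r = 1 is only reachable with "
                "noise_sd = 0, r ≤ 0 is not a community)"
            )
        if not 0.0 <= self.between_community_r < self.within_community_r:
            raise GeneratorError(
                f"network {self.name!r}: need 0 ≤ between_community_r "
                f"< within_community_r, got {self.between_community_r} "
                f"vs {self.within_community_r}"
            )
        if not 0.0 < self.low_freq_fraction < 1.0:
            raise GeneratorError(
                f"network {self.name!r}: low_freq_fraction must lie in (0, 1)"
            )


def default_networks() -> list[NetworkSpec]:
    """The six default networks.

    Sizes follow the empirical ordering of real RSNs (DMN largest, SMN
    smallest) at desk scale.  Cognitive networks are more modular (more
    communities, weaker inter-community coupling) and carry more
    low-frequency power; perceptual networks are denser and flatter.
    Low-frequency fractions follow the empirical ordering
    DMN > VN > CEN > DAN > SMN > AN.
    """
    cog = dict(group=COGNITIVE, n_communities=5,
               within_community_r=0.48, between_community_r=0.15)
    per = dict(group=PERCEPTUAL, n_communities=3,
               within_community_r=0.44, between_community_r=0.30)
    return [
        NetworkSpec(name="CEN", n_voxels=180, low_freq_fraction=0.72, **cog),
        NetworkSpec(name="DAN", n_voxels=190, low_freq_fraction=0.70, **cog),
        NetworkSpec(name="DMN", n_voxels=260, low_freq_fraction=0.80, **cog),
        NetworkSpec(name="SMN", n_voxels=150, low_freq_fraction=0.62, **per),
        NetworkSpec(name="AN", n_voxels=170, low_freq_fraction=0.60, **per),
        NetworkSpec(name="VN", n_voxels=160, low_freq_fraction=0.74, **per),
    ]


def retained_volumes(acquired: int = ACQUIRED_VOLUMES,
                     discarded: int = DUMMY_VOLUMES) -> int:
    """Number of volumes kept for analysis after dummy-scan removal."""
    if discarded < 0 or discarded >= acquired:
        raise GeneratorError("discarded volumes must lie in [0, acquired)")
    return acquired - discarded


@dataclass
class GeneratorConfig:
    """Full configuration of the synthetic cohort generator."""

    n_subjects: int = 12
    n_timepoints: int = retained_volumes()
    tr: float = 2.0
    networks: list[NetworkSpec] = field(default_factory=default_networks)
    overlap_fraction: float = 0.10
    noise_sd: float = 1.0
    nuisance_amplitudes: dict[str, float] = field(default_factory=lambda: {
        "motion": 0.4, "wm": 0.3, "ventricle": 0.3, "global": 0.5,
    })
    grid_shape: tuple[int, int, int] = (24, 24, 12)
    voxel_size_mm: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise GeneratorError("n_subjects must be ≥ 1")
        if self.n_timepoints < 16:
            raise GeneratorError("n_timepoints must be ≥ 16")
        if self.tr <= 0:
            raise GeneratorError("tr must be positive")
        if not 0.0 <= self.overlap_fraction <= 0.5:
            raise GeneratorError("overlap_fraction must lie in [0, 0.5]")
        if self.noise_sd < 0:
            raise GeneratorError("noise_sd must be ≥ 0")
        if not self.networks:
            raise GeneratorError("at least one network is required")
        names = [n.name for n in self.networks]
        if len(set(names)) != len(names):
            raise GeneratorError("network names must be unique")
        for spec in self.networks:
            spec.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["networks"] = [dataclasses.asdict(n) for n in self.networks]
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "networks" in d:
            d["networks"] = [NetworkSpec(**n) for n in d["networks"]]
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


@dataclass
class RSNAtlas:
    """Multi-label voxel atlas: one boolean mask per network.

    A voxel may belong to more than one network (overlap); downstream
    analysis excludes such voxels.
    """

    shape: tuple[int, int, int]
    masks: dict[str, np.ndarray]          # name -> bool volume
    groups: dict[str, str]                # name -> cognitive|perceptual

    @property
    def names(self) -> list[str]:
        return list(self.masks)

    def label_counts(self) -> np.ndarray:
        """Number of network labels carried by each voxel."""
        counts = np.zeros(self.shape, dtype=np.int16)
        for m in self.masks.values():
            counts += m
        return counts

    def voxels(self, name: str) -> np.ndarray:
        """All voxel coordinates of a network, shape (k, 3)."""
        return np.argwhere(self.masks[name])

    def multi_label_fraction(self, name: str) -> float:
        counts = self.label_counts()
        mask = self.masks[name]
        return float((counts[mask] > 1).mean())

    def validate(self) -> None:
        for name, m in self.masks.items():
            if m.shape != self.shape:
                raise GeneratorError(f"mask {name!r} has wrong shape")
            if not m.any():
                raise GeneratorError(f"network {name!r} has no voxels")


@dataclass
class BoldDataset:
    """One subject's 4-D volume plus nuisance channels.

    ``clean_latents`` carries the noise-free community latents actually
    used for this subject (network -> (n_communities, t) array); it is not
    serialised and exists so that spectral calibration can be verified
    against the clean signal.
    """

    subject_id: str
    volumes: np.ndarray                   # (x, y, z, t) float32
    tr: float
    motion: np.ndarray                    # (t, 6)
    wm_signal: np.ndarray                 # (t,)
    ventricle_signal: np.ndarray          # (t,)
    global_signal: np.ndarray             # (t,)
    clean_latents: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    clean_voxels: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    #: per network, each voxel's primary community (aligned with the
    #: atlas voxel order); diagnostic only, not serialised
    communities: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def n_timepoints(self) -> int:
        return self.volumes.shape[-1]

    def validate(self) -> None:
        if self.motion.shape != (self.n_timepoints, 6):
            raise GeneratorError("motion table must be t×6")
        for name in ("wm_signal", "ventricle_signal", "global_signal"):
            if getattr(self, name).shape != (self.n_timepoints,):
                raise GeneratorError(f"{name} must have length t")
        if not np.isfinite(self.volumes).all():
            raise GeneratorError("volumes contain non-finite values")


# ---------------------------------------------------------------------------
# atlas construction
# ---------------------------------------------------------------------------

def _ring_centres(shape: tuple[int, int, int], k: int) -> np.ndarray:
    """Place k blob centres on an ellipse in the central axial slab."""
    nx, ny, nz = shape
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    rx, ry = nx / 3.0, ny / 3.0
    ang = 2 * np.pi * np.arange(k) / k
    centres = np.stack(
        [cx + rx * np.cos(ang), cy + ry * np.sin(ang), np.full(k, cz)], axis=1
    )
    return centres


def _claim_nearest(coords: np.ndarray, centre: np.ndarray, claimed: np.ndarray,
                   k: int) -> np.ndarray:
    """Indices (into coords) of the k unclaimed voxels nearest to centre."""
    d2 = ((coords - centre) ** 2).sum(axis=1).astype(float)
    d2[claimed] = np.inf
    order = np.argsort(d2, kind="stable")
    picked = order[:k]
    if k and not np.isfinite(d2[picked[-1]]):
        raise GeneratorError("grid exhausted while placing voxels")
    return picked


def generate_atlas(config: GeneratorConfig) -> RSNAtlas:
    """Build the multi-label atlas: compact blobs on a ring, with each
    ring-adjacent pair of networks sharing a blob of voxels so that every
    network's multi-label fraction is ≈ ``overlap_fraction``.

    Deterministic for a fixed ``config.seed``.
    """
    config.validate()
    shape = config.grid_shape
    n_nets = len(config.networks)
    total_needed = sum(n.n_voxels for n in config.networks)
    n_grid = int(np.prod(shape))
    if total_needed > n_grid:
        biggest = max(config.networks, key=lambda n: n.n_voxels)
        raise GeneratorError(
            f"grid {shape} has {n_grid} voxels, cannot host {total_needed} "
            f"network voxels (largest request: {biggest.name!r} "
            f"with {biggest.n_voxels})"
        )

    coords = np.argwhere(np.ones(shape, dtype=bool)).astype(float)
    centres = _ring_centres(shape, n_nets)
    claimed = np.zeros(len(coords), dtype=bool)
    label_sets: dict[str, list[np.ndarray]] = {n.name: [] for n in config.networks}

    # shared blobs between ring-adjacent pairs (i, i+1 mod n)
    if config.overlap_fraction > 0 and n_nets > 1:
        for i in range(n_nets if n_nets > 2 else 1):
            j = (i + 1) % n_nets
            a, b = config.networks[i], config.networks[j]
            s = int(round(config.overlap_fraction * (a.n_voxels + b.n_voxels) / 4))
            if s == 0:
                continue
            mid = (centres[i] + centres[j]) / 2
            try:
                picked = _claim_nearest(coords, mid, claimed, s)
            except GeneratorError as exc:
                raise GeneratorError(
                    f"grid too small for shared region between "
                    f"{a.name!r} and {b.name!r}"
                ) from exc
            claimed[picked] = True
            label_sets[a.name].append(picked)
            label_sets[b.name].append(picked)

    # exclusive remainders, grown from each centre
    for spec, centre in zip(config.networks, centres):
        have = sum(len(p) for p in label_sets[spec.name])
        need = spec.n_voxels - have
        if need < 0:
            raise GeneratorError(
                f"network {spec.name!r}: overlap regions exceed n_voxels"
            )
        try:
            picked = _claim_nearest(coords, centre, claimed, need)
        except GeneratorError as exc:
            raise GeneratorError(
                f"grid {shape} too small to host network {spec.name!r} "
                f"({spec.n_voxels} voxels requested)"
            ) from exc
        claimed[picked] = True
        label_sets[spec.name].append(picked)

    masks: dict[str, np.ndarray] = {}
    for spec in config.networks:
        m = np.zeros(shape, dtype=bool)
        idx = np.concatenate(label_sets[spec.name])
        ii = coords[idx].astype(int)
        m[ii[:, 0], ii[:, 1], ii[:, 2]] = True
        masks[spec.name] = m

    atlas = RSNAtlas(shape=shape, masks=masks,
                     groups={n.name: n.group for n in config.networks})
    atlas.validate()
    return atlas


# ---------------------------------------------------------------------------
# spectrally shaped latents
# ---------------------------------------------------------------------------

def shaped_latent(rng: np.random.Generator, t: int, tr: float,
                  low_freq_fraction: float,
                  band: tuple[float, float] = DEFAULT_BAND) -> np.ndarray:
    """Unit-variance, zero-mean series whose in-band power fraction equals
    ``low_freq_fraction`` exactly (in the one-sided periodogram convention
    used by :mod:`rsntopo.spectral`).

    The series is synthesised in the frequency domain: complex Gaussian
    coefficients at every positive frequency, then the in-band and
    out-of-band groups are rescaled to the target power split.
    """
    if not 0.0 < low_freq_fraction < 1.0:
        raise GeneratorError("low_freq_fraction must lie in (0, 1)")
    freqs = rfftfreq(t, d=tr)
    coef = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    coef[0] = 0.0                                  # no DC
    if t % 2 == 0:
        coef[-1] = coef[-1].real                   # Nyquist bin is real
    inband = (freqs >= band[0]) & (freqs <= band[1])
    outband = ~inband & (freqs > 0)
    if not inband.any() or not outband.any():
        raise GeneratorError("band leaves no in-band or out-of-band frequencies")
    # one-sided periodogram weights: interior bins count twice, the (even-t)
    # Nyquist bin once — matching rsntopo.spectral.periodogram, so the
    # realized band fraction equals the request exactly
    w = np.full(len(freqs), 2.0)
    w[0] = 1.0
    if t % 2 == 0:
        w[-1] = 1.0
    p_in = float((w[inband] * np.abs(coef[inband]) ** 2).sum())
    p_out = float((w[outband] * np.abs(coef[outband]) ** 2).sum())
    coef[inband] *= np.sqrt(low_freq_fraction / p_in)
    coef[outband] *= np.sqrt((1.0 - low_freq_fraction) / p_out)
    x = irfft(coef, n=t)
    return x / x.std()


def _bandlimited_noise(rng: np.random.Generator, t: int, tr: float,
                       fmax: float) -> np.ndarray:
    """Unit-variance noise confined below ``fmax`` Hz (nuisance channels)."""
    freqs = rfftfreq(t, d=tr)
    coef = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    coef[0] = 0.0
    coef[freqs > fmax] = 0.0
    x = irfft(coef, n=t)
    return x / x.std()


# ---------------------------------------------------------------------------
# community geometry
# ---------------------------------------------------------------------------

def community_layout(atlas: RSNAtlas, config: GeneratorConfig,
                     rng: np.random.Generator | None = None):
    """Per network: community centres (farthest-point sampling over the
    network's voxels) and per-voxel mixing weights over communities.

    Returns ``{name: (coords, weights, primary)}`` with coords (k, 3) int,
    weights (k, n_communities) rows summing to 1, and primary (k,) the
    argmax community of each voxel.

    The cohort generator draws one layout per subject (functional
    subdivisions vary across individuals), so network-level geometry does
    not induce systematic across-subject effects; without an explicit
    ``rng`` the layout is the deterministic config-seed one.
    """
    out = {}
    if rng is None:
        rng = np.random.default_rng([config.seed, 7])
    for spec in config.networks:
        coords = atlas.voxels(spec.name).astype(float)
        k = len(coords)
        n_c = min(spec.n_communities, k)
        centres_idx = [int(rng.integers(k))]
        for _ in range(1, n_c):
            d2 = np.min(
                ((coords[:, None, :] - coords[centres_idx][None, :, :]) ** 2).sum(-1),
                axis=1,
            )
            centres_idx.append(int(np.argmax(d2)))
        centres = coords[centres_idx]
        d2 = ((coords[:, None, :] - centres[None, :, :]) ** 2).sum(-1)
        nearest = np.sqrt(d2.min(axis=1))
        rho = max(KERNEL_WIDTH_SCALE * float(np.median(nearest)), 1.0)
        w = np.exp(-d2 / (2 * rho ** 2))
        w /= w.sum(axis=1, keepdims=True)
        out[spec.name] = (coords.astype(int), w, np.argmax(w, axis=1))
    return out


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _clean_voxel_signals(rng: np.random.Generator, spec: NetworkSpec,
                         weights: np.ndarray, t: int, tr: float,
                         group_latent: np.ndarray):
    """Clean (noise-free) unit-variance voxel signals for one network.

    Community latents: s_c = √b·g + √(1−b)·e_c with g the network latent,
    which itself carries a ±√CROSS_GROUP_COUPLING loading on the shared
    cohort latent.  Voxel signal: weighted latent mixture, renormalised to
    unit variance using the latent covariance Σ = (1−b)·I + b·J.
    """
    b = spec.between_community_r
    n_c = weights.shape[1]
    sign = 1.0 if spec.group == COGNITIVE else -1.0
    c = CROSS_GROUP_COUPLING
    g_own = shaped_latent(rng, t, tr, spec.low_freq_fraction)
    g_net = np.sqrt(c) * sign * group_latent + np.sqrt(1 - c) * g_own
    lat = np.empty((n_c, t))
    for ci in range(n_c):
        e = shaped_latent(rng, t, tr, spec.low_freq_fraction)
        lat[ci] = np.sqrt(b) * g_net + np.sqrt(1 - b) * e
    x = weights @ lat                                       # (k, t)
    # Var(w·s) = w'Σw with Σ = (1−b)I + bJ (unit-variance latents)
    var = (1 - b) * (weights ** 2).sum(axis=1) + b * weights.sum(axis=1) ** 2
    x /= np.sqrt(var)[:, None]
    return x, lat


def generate_cohort(config: GeneratorConfig,
                    atlas: RSNAtlas | None = None) -> list[BoldDataset]:
    """Generate the full multi-subject cohort.

    Returns one :class:`BoldDataset` per subject.  Fixed
    ``config.seed`` gives a byte-identical cohort.
    """
    config.validate()
    if atlas is None:
        atlas = generate_atlas(config)
    atlas.validate()
    for spec in config.networks:
        if spec.name not in atlas.masks:
            raise GeneratorError(f"atlas lacks network {spec.name!r}")

    t, tr = config.n_timepoints, config.tr
    amps = config.nuisance_amplitudes
    # Mixing weight solved from the target r at the reference noise SD of
    # 1: corr(same community) = g²/(g² + noise_sd²), which equals
    # within_community_r at noise_sd = 1 and decreases monotonically as
    # noise_sd grows.  noise_sd = 0 returns the clean latents (r = 1).
    if config.noise_sd == 0:
        g_mix = {spec.name: 1.0 for spec in config.networks}
    else:
        g_mix = {
            spec.name: np.sqrt(
                spec.within_community_r / (1 - spec.within_community_r))
            for spec in config.networks
        }

    cohort = []
    for si in range(config.n_subjects):
        rng = np.random.default_rng([config.seed, 11, si])
        # subject-specific community geometry
        layout = community_layout(atlas, config, rng=rng)
        # nuisance channels
        motion = np.cumsum(rng.standard_normal((t, 6)), axis=0)
        motion -= motion.mean(axis=0)
        motion /= motion.std(axis=0)
        wm = _bandlimited_noise(rng, t, tr, 0.1)
        vent = _bandlimited_noise(rng, t, tr, 0.1)
        glob = _bandlimited_noise(rng, t, tr, 0.1)
        group_latent = shaped_latent(rng, t, tr, 0.70)

        vol_sum = np.zeros(atlas.shape + (t,), dtype=np.float64)
        vol_cnt = np.zeros(atlas.shape, dtype=np.int16)
        latents: dict[str, np.ndarray] = {}
        cleans: dict[str, np.ndarray] = {}
        comms: dict[str, np.ndarray] = {}
        for spec in config.networks:
            coords, weights, primary = layout[spec.name]
            comms[spec.name] = primary
            x, lat = _clean_voxel_signals(rng, spec, weights, t, tr, group_latent)
            latents[spec.name] = lat
            cleans[spec.name] = x
            k = len(coords)
            noise = rng.standard_normal((k, t)) if config.noise_sd else 0.0
            y = g_mix[spec.name] * x + config.noise_sd * noise
            # nuisance contamination: per-voxel random loadings
            load_m = rng.normal(scale=amps.get("motion", 0.0) / np.sqrt(6),
                                size=(k, 6))
            y = y + load_m @ motion.T
            y = y + amps.get("wm", 0.0) * rng.normal(1.0, 0.2, size=(k, 1)) * wm
            y = y + amps.get("ventricle", 0.0) * rng.normal(1.0, 0.2, size=(k, 1)) * vent
            y = y + amps.get("global", 0.0) * rng.normal(1.0, 0.2, size=(k, 1)) * glob
            vol_sum[coords[:, 0], coords[:, 1], coords[:, 2]] += y
            vol_cnt[coords[:, 0], coords[:, 1], coords[:, 2]] += 1

        # overlap voxels: average of their parent networks' signals
        nz = vol_cnt > 0
        vol_sum[nz] /= vol_cnt[nz][:, None]
        # background voxels: plain noise so volumes look brain-like
        bg_sd = config.noise_sd if config.noise_sd else 1.0
        bg = rng.standard_normal((int((~nz).sum()), t)) * bg_sd
        vol_sum[~nz] = bg
        vol = (vol_sum + 100.0).astype(np.float32)        # baseline offset

        ds = BoldDataset(
            subject_id=f"sub-{si + 1:02d}",
            volumes=vol, tr=tr, motion=motion,
            wm_signal=wm, ventricle_signal=vent, global_signal=glob,
            clean_latents=latents, clean_voxels=cleans, communities=comms,
        )
        ds.validate()
        cohort.append(ds)
    return cohort
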