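"""Seeded two-channel nuclear texture phantoms and immunogold count tables.

A phantom nucleus is an elliptical mask holding two correlated-noise
intensity fields standing in for the activating (green, H3K4me3) and
repressive (red, H3K27me3) histone marks.  A single latent
chromatin-openness parameter θ ∈ [0, 1] drives everything a texture
pipeline can see:

* granularity — both channels are Gaussian random fields whose spatial
  correlation length grows as chromatin closes (θ → 0), the red channel
  faster than the green;
* peripheral aggregation — a radially increasing weight concentrates the
  red (heterochromatin-like) signal at the nuclear rim;
* channel balance — the expected green share of total photons equals θ;
* shot noise — per-pixel Poisson counts at a configurable photon gain.

Every phantom is reproducible from its spec and seed; cohort members get
counter-based child seeds so a cohort is order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import BadSpecError
from .image import Channel, ImageStack, NucleusImage

#: In-mask mean photon count of a channel at share 0.5 (see docs/methods.md).
DEFAULT_PHOTON_GAIN = 200.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic nucleus.

    Correlation lengths and peripheral bias left as None are derived from
    θ: ℓ_green = 1.5 + 3(1-θ), ℓ_red = 1.5 + 6(1-θ) px, and
    peripheral_bias = 0.8(1-θ) — closing chromatin coarsens the texture
    and pushes the repressive mark toward the nuclear perimeter.
    """

    openness: float = 0.5
    shape: tuple[int, int] = (256, 256)
    semi_axes: tuple[float, float] | None = None   # default scales with shape
    axis_jitter: float = 0.1
    corr_len_green: float | None = None
    corr_len_red: float | None = None
    peripheral_bias: float | None = None
    photon_gain: float = DEFAULT_PHOTON_GAIN
    pixel_size_um: float = 23.25 / 1024
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.openness <= 1.0:
            raise BadSpecError("openness must lie in [0, 1]")
        if self.semi_axes is not None and (
            self.semi_axes[0] <= 0 or self.semi_axes[1] <= 0
        ):
            raise BadSpecError("semi-axes must be positive")
        if self.photon_gain <= 0:
            raise BadSpecError("photon_gain must be positive")

    @property
    def axes(self) -> tuple[float, float]:
        """Ellipse semi-axes; defaults to (0.35, 0.27) of the image sides
        ((90, 70) px at 256 x 256)."""
        if self.semi_axes is not None:
            return self.semi_axes
        return (0.3516 * self.shape[0], 0.2734 * self.shape[1])

    @property
    def ell_green(self) -> float:
        if self.corr_len_green is not None:
            return self.corr_len_green
        return 1.5 + 3.0 * (1.0 - self.openness)

    @property
    def ell_red(self) -> float:
        if self.corr_len_red is not None:
            return self.corr_len_red
        return 1.5 + 6.0 * (1.0 - self.openness)

    @property
    def bias_red(self) -> float:
        if self.peripheral_bias is not None:
            return self.peripheral_bias
        return 0.8 * (1.0 - self.openness)


@dataclass(frozen=True)
class Phantom:
    """One synthetic nucleus: noisy channels, noiseless fields, mask."""

    green: np.ndarray        # Poisson photon counts
    red: np.ndarray
    lam_green: np.ndarray    # noiseless expected-count fields
    lam_red: np.ndarray
    mask: np.ndarray
    spec: PhantomSpec

    def stacks(self) -> tuple[ImageStack, ImageStack]:
        """Wrap the channels as single-plane image stacks."""
        return (
            ImageStack(self.green[None], Channel.GREEN_K4, self.spec.pixel_size_um),
            ImageStack(self.red[None], Channel.RED_K27, self.spec.pixel_size_um),
        )

    def nucleus_images(self) -> tuple[NucleusImage, NucleusImage]:
        """Channels as masked 2-D images (ground-truth mask attached)."""
        return (
            NucleusImage(self.green, self.mask, self.spec.pixel_size_um,
                         Channel.GREEN_K4),
            NucleusImage(self.red, self.mask, self.spec.pixel_size_um,
                         Channel.RED_K27),
        )


def _grf(rng: np.random.Generator, shape: tuple[int, int], ell: float) -> np.ndarray:
    """Gaussian random field by low-pass filtering white noise, unit std."""
    noise = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(noise, sigma=ell, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def synth_nucleus(spec: PhantomSpec) -> Phantom:
    """Generate one two-channel phantom nucleus from a spec.

    The noiseless field of each channel has in-mask mean
    ``2 * share * photon_gain`` photons (share = θ for green, 1-θ for
    red), so the green fraction of the total expected signal is θ and the
    Poisson relative error shrinks as 1/sqrt(photon_gain).
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    a = spec.axes[0] * (1.0 + spec.axis_jitter * rng.uniform(-1, 1))
    b = spec.axes[1] * (1.0 + spec.axis_jitter * rng.uniform(-1, 1))
    phi = rng.uniform(0.0, np.pi)
    yy, xx = np.mgrid[0:rows, 0:cols]
    yc, xc = (rows - 1) / 2.0, (cols - 1) / 2.0
    u = (xx - xc) * np.cos(phi) + (yy - yc) * np.sin(phi)
    v = -(xx - xc) * np.sin(phi) + (yy - yc) * np.cos(phi)
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)   # elliptical radius, 1 at rim
    mask = rho <= 1.0
    if not mask.any():
        raise BadSpecError("semi-axes too small for the image shape")

    base = 2.0  # mean offset in units of field std; keeps rectification mild
    g_field = np.clip(base + _grf(rng, spec.shape, spec.ell_green), 0.0, None)
    r_field = np.clip(base + _grf(rng, spec.shape, spec.ell_red), 0.0, None)
    # radially increasing heterochromatin weight
    w = (1.0 - spec.bias_red) + spec.bias_red * np.clip(rho, 0.0, 1.0) ** 2
    r_field = r_field * w

    theta = spec.openness
    lam_g = np.zeros(spec.shape)
    lam_r = np.zeros(spec.shape)
    if g_field[mask].mean() > 0:
        lam_g[mask] = g_field[mask] / g_field[mask].mean() * (
            2.0 * theta * spec.photon_gain
        )
    if r_field[mask].mean() > 0:
        lam_r[mask] = r_field[mask] / r_field[mask].mean() * (
            2.0 * (1.0 - theta) * spec.photon_gain
        )
    green = rng.poisson(lam_g).astype(float)
    red = rng.poisson(lam_r).astype(float)
    return Phantom(green=green, red=red, lam_green=lam_g, lam_red=lam_r,
                   mask=mask, spec=spec)


@dataclass(frozen=True)
class CohortMember:
    phantom: Phantom
    label: str
    openness: float


@dataclass(frozen=True)
class SyntheticCohort:
    """Labeled phantoms plus the provenance needed to regenerate them."""

    members: tuple[CohortMember, ...]
    base_spec: PhantomSpec
    theta_list: tuple[float, ...]
    n_per_condition: int
    master_seed: int

    def __len__(self) -> int:
        return len(self.members)

    def provenance(self) -> dict:
        return {
            "theta_list": list(self.theta_list),
            "n_per_condition": self.n_per_condition,
            "master_seed": self.master_seed,
            "shape": list(self.base_spec.shape),
            "photon_gain": self.base_spec.photon_gain,
            "member_seeds": [m.phantom.spec.seed for m in self.members],
        }


def _child_seed(master_seed: int, condition_index: int, member_index: int) -> int:
    """Counter-based child seed: order-independent across the cohort."""
    ss = np.random.SeedSequence(
        master_seed, spawn_key=(condition_index, member_index)
    )
    return int(ss.generate_state(1)[0] % (2**31))


def synth_cohort(
    theta_list,
    n_per_condition: int,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    labels: list[str] | None = None,
) -> SyntheticCohort:
    """Generate ``n_per_condition`` phantoms at each openness value."""
    theta_list = tuple(float(t) for t in theta_list)
    if not theta_list:
        raise BadSpecError("theta_list must be non-empty")
    if n_per_condition < 1:
        raise BadSpecError("n_per_condition must be >= 1")
    base_spec = base_spec or PhantomSpec()
    if labels is None:
        labels = [f"theta_{t:g}" for t in theta_list]
    members = []
    for ci, (theta, label) in enumerate(zip(theta_list, labels)):
        for i in range(n_per_condition):
            spec = replace(
                base_spec, openness=theta, seed=_child_seed(seed, ci, i)
            )
            members.append(
                CohortMember(phantom=synth_nucleus(spec), label=label,
                             openness=theta)
            )
    return SyntheticCohort(
        members=tuple(members),
        base_spec=base_spec,
        theta_list=theta_list,
        n_per_condition=n_per_condition,
        master_seed=seed,
    )


def synth_iem(
    theta: float,
    n_eu: int = 100,
    n_het: int = 100,
    contrast: float = 4.0,
    seed: int = 0,
):
    """Synthetic immunogold counts whose expected log2 openness index
    increases strictly with θ.

    In euchromatic regions each of ``n_eu`` particles is H3K4me3 with
    probability σ(κ(θ-0.5)), where σ is the logistic function and κ the
    contrast; in heterochromatic regions each of ``n_het`` particles is
    H3K27me3 with the mirrored probability σ(κ(0.5-θ)), so the repressive
    mark loses ground in heterochromatin as chromatin opens.  The expected
    log2 index is then ≈ 2κ(θ-0.5)/ln 2: zero at θ = 0.5 and strictly
    increasing in θ.
    """
    from .analytics import IEMCounts

    if n_eu < 1 or n_het < 1:
        raise BadSpecError("n_eu and n_het must be >= 1")
    if contrast <= 0:
        raise BadSpecError("contrast must be positive")
    rng = np.random.default_rng(seed)
    p_open = 1.0 / (1.0 + np.exp(-contrast * (theta - 0.5)))
    k4_eu = int(rng.binomial(n_eu, p_open))
    k27_het = int(rng.binomial(n_het, 1.0 - p_open))
    return IEMCounts(
        k4_eu=k4_eu,
        k27_eu=n_eu - k4_eu,
        k4_het=n_het - k27_het,
        k27_het=k27_het,
    )
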