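"""Scenario presets for the synthetic movie/spread generator.

Each preset encodes one biological condition of papillar or wing-disc
mitosis after ectopic genome reduplication:

* ``pre_division`` — fixed cells before the first division: kinetochores
  clustered into about the haploid number of foci (4 w.p. 0.9, 5 w.p. 0.1;
  mean 4.1).
* ``post_division`` — fixed cells after the first division: dispersed
  sister-pair foci (14/15/16/17 w.p. 0.3/0.4/0.2/0.1; mean 15.1).
* ``wt_timing`` / ``mad2_timing`` — 1-min-interval live movies of the first
  division; NEBD-to-anaphase duration truncated-normal with mean 17.1 min
  (wild type) or 14.0 min (mad2, checkpoint-compromised); mad2 divisions
  fail to complete sister dispersal with probability 0.3, and incomplete
  dispersal always produces a DNA bridge.
* ``diplo_division`` — diplochromosome (reduplicated) divisions: metaphase
  twice the wild-type baseline and a planted segregation error (lagging
  chromosome or bridge) with probability 0.80.
* ``mad2_diplo`` — diplochromosome division without a functional
  checkpoint: planted error probability 1.0.
* ``tetraploid_no_diplo`` — tetraploid divisions whose chromosomes fully
  separated before mitosis: low error probability (0.10).
* ``colcemid_like`` — sister dispersal without any segregation (spindle
  poisoned): clusteredness completes its decline but no anaphase occurs.
* ``hs10_metaphase`` — tetraploid metaphase spreads: diplochromosome
  configuration w.p. 0.96, otherwise fully separated tetraploid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .render import NoiseParams

HAPLOID_N = {"female": 4, "male": 5}  # X/Y un-pairing gives males 5 groups

SPREAD_CLASSES = (
    "euploid_diploid",
    "euploid_tetraploid",
    "euploid_diplo_tetraploid",
    "aneuploid_tetraploid",
    "polytene",
    "clumped",
    "separated",
)


@dataclass(frozen=True)
class DiscreteDist:
    """Finite discrete distribution over integers or labels."""

    values: tuple
    probs: tuple

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if len(self.values) != len(p):
            raise ValueError("values and probs length mismatch")
        if np.any(p < 0) or np.any(p > 1) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must lie in [0,1] and sum to 1")

    def sample(self, rng: np.random.Generator):
        i = rng.choice(len(self.values), p=np.asarray(self.probs, dtype=float))
        return self.values[i]

    @property
    def mean(self) -> float:
        return float(np.dot(self.values, self.probs))


@dataclass(frozen=True)
class TruncNormal:
    """Normal(mean, sd) truncated to [lo, hi]."""

    mean: float
    sd: float
    lo: float
    hi: float

    def sample(self, rng: np.random.Generator) -> float:
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return float(stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd,
                                         random_state=rng))


@dataclass(frozen=True)
class UniformDist:
    lo: float
    hi: float

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(self.lo, self.hi))


@dataclass(frozen=True)
class DispersalModel:
    """How initial kinetochore clusters split into sister-pair foci.

    ``incomplete_prob`` is the probability that a cell fails to finish
    dispersal; in such cells a fixed ``unsplit_fraction`` of clusters never
    split (at least one cluster).
    """

    incomplete_prob: float = 0.0
    unsplit_fraction: float = 0.25
    child_scatter_px: float = 2.5


@dataclass(frozen=True)
class ErrorRates:
    """Probabilities of planted anaphase errors (mutually exclusive draw)."""

    error_prob: float = 0.0       # probability that the division has any error
    bridge_given_error: float = 0.5

    def __post_init__(self):
        for p in (self.error_prob, self.bridge_given_error):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0,1]")


@dataclass(frozen=True)
class Preset:
    """One simulated biological condition; see the module docstring."""

    name: str
    kind: str = "movie"  # movie | spread
    frame_interval: float = 2.0        # minutes
    n_frames: int = 30
    image_shape: tuple = (96, 96)
    cluster_count_dist: DiscreteDist = DiscreteDist((4,), (1.0,))
    pairs_per_cluster: int = 4         # sister-pair foci hidden in each cluster
    nebd_time_dist: UniformDist | None = UniformDist(6.0, 9.0)
    duration_dist: TruncNormal | None = TruncNormal(17.1, 2.5, 10.0, 26.0)
    metaphase_len_dist: TruncNormal | None = TruncNormal(6.0, 1.0, 4.0, 9.0)
    dispersal: DispersalModel = DispersalModel()
    error_rates: ErrorRates = ErrorRates()
    segregate: bool = True             # False: SIRS without anaphase
    static: bool = False               # True: no events at all (fixed cell)
    spread_class_mix: DiscreteDist | None = None
    noise: NoiseParams = field(default_factory=NoiseParams)
    psf_sigma: float = 1.5
    kinetochore_amp: float = 60.0      # peak height of a single kinetochore
    pole_speed: float = 6.0            # px/min of each pole (1.2 um/min at 0.2 um/px)
    pole_cap_px: float = 30.0          # poleward travel stops at this offset

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def _movie_noise(max_amp: float) -> NoiseParams:
    """Default noise: background 5% and read sd 2% of the peak amplitude."""
    return NoiseParams(background=0.05 * max_amp, read_sd=0.02 * max_amp, poisson=True)


def _build_presets() -> dict:
    p = {}
    # --- fixed-cell foci-counting scenarios (Fig-3E-like) -------------------
    # A pre-division cluster hides 4 sister pairs; peak amplitude 8 kinetochores.
    pre_amp = 8 * 60.0
    p["pre_division"] = Preset(
        name="pre_division", kind="movie", static=True, segregate=False,
        frame_interval=1.0, n_frames=2, image_shape=(64, 64),
        cluster_count_dist=DiscreteDist((4, 5), (0.9, 0.1)),
        pairs_per_cluster=4, nebd_time_dist=None, duration_dist=None,
        metaphase_len_dist=None, noise=_movie_noise(pre_amp),
    )
    post_amp = 2 * 60.0  # dispersed sister-pair focus
    p["post_division"] = Preset(
        name="post_division", kind="movie", static=True, segregate=False,
        frame_interval=1.0, n_frames=2, image_shape=(80, 80),
        cluster_count_dist=DiscreteDist((14, 15, 16, 17), (0.3, 0.4, 0.2, 0.1)),
        pairs_per_cluster=1, nebd_time_dist=None, duration_dist=None,
        metaphase_len_dist=None, noise=_movie_noise(post_amp),
    )
    # --- first-division timing movies --------------------------------------
    # Camera noise is referenced to the canonical imaged object, a dispersed
    # sister-pair focus (2 kinetochores), so dim post-anaphase kinetochores
    # stay several sigma above background.
    amp = 2 * 60.0
    p["wt_timing"] = Preset(
        name="wt_timing", frame_interval=1.0, n_frames=44,
        cluster_count_dist=DiscreteDist((4,), (1.0,)), pairs_per_cluster=4,
        nebd_time_dist=UniformDist(6.0, 9.0),
        duration_dist=TruncNormal(17.1, 2.5, 10.0, 26.0),
        metaphase_len_dist=TruncNormal(6.0, 1.0, 4.0, 9.0),
        noise=_movie_noise(amp), psf_sigma=1.0,
    )
    p["mad2_timing"] = replace(
        p["wt_timing"], name="mad2_timing", n_frames=40,
        duration_dist=TruncNormal(14.0, 2.0, 8.0, 22.0),
        metaphase_len_dist=TruncNormal(4.5, 1.0, 3.0, 6.5),
        dispersal=DispersalModel(incomplete_prob=0.3),
        # incomplete dispersal forces a planted bridge (handled in movie.py)
    )
    # --- diplochromosome divisions (2-min frames, wing-disc-like) -----------
    diplo_amp = 2 * 60.0  # noise referenced to one sister-pair focus
    p["diplo_division"] = Preset(
        name="diplo_division", frame_interval=2.0, n_frames=26,
        cluster_count_dist=DiscreteDist((8,), (1.0,)), pairs_per_cluster=2,
        nebd_time_dist=UniformDist(4.0, 8.0),
        duration_dist=TruncNormal(20.0, 3.0, 14.0, 30.0),
        metaphase_len_dist=TruncNormal(12.0, 2.0, 8.0, 16.0),
        error_rates=ErrorRates(error_prob=0.80),
        noise=_movie_noise(diplo_amp), psf_sigma=1.0,
    )
    p["mad2_diplo"] = replace(
        p["diplo_division"], name="mad2_diplo",
        error_rates=ErrorRates(error_prob=1.0),
    )
    p["tetraploid_no_diplo"] = replace(
        p["diplo_division"], name="tetraploid_no_diplo",
        cluster_count_dist=DiscreteDist((16,), (1.0,)), pairs_per_cluster=1,
        metaphase_len_dist=TruncNormal(6.0, 1.0, 4.0, 9.0),
        duration_dist=TruncNormal(17.0, 2.5, 12.0, 24.0),
        error_rates=ErrorRates(error_prob=0.10),
    )
    p["colcemid_like"] = replace(
        p["wt_timing"], name="colcemid_like", segregate=False, n_frames=36,
        error_rates=ErrorRates(error_prob=0.0),
    )
    # --- karyotype spreads ---------------------------------------------------
    p["hs10_metaphase"] = Preset(
        name="hs10_metaphase", kind="spread", image_shape=(200, 200),
        spread_class_mix=DiscreteDist(
            ("euploid_diplo_tetraploid", "euploid_tetraploid"), (0.96, 0.04)),
        psf_sigma=1.0, noise=NoiseParams(background=10.0, read_sd=4.0, poisson=True),
    )
    return p


PRESETS = _build_presets()


def get_preset(name: str) -> Preset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; known: {sorted(PRESETS)}") from None
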