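"""Cohort-level measurements over synthetic study conditions.

Each function generates a cohort from one preset, runs the relevant
quantification stages exactly as they would run on real movies, and
returns the summary quantity of interest (mean focus count, mean
NEBD-to-anaphase duration, error percentage, diplochromosome percentage).
Seeds are expanded from a single cohort seed via ``SeedSequence`` so each
cell is independent but the whole cohort is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError
from .foci import count_resolvable_foci, segment_foci, segment_movie
from .karyotype import classify_image
from .plate import score_errors
from .synthetic import (generate_cell_image, generate_movie,
                        generate_spread_from_preset, get_preset)
from .timing import detect_anaphase, detect_nebd, geminin_trace, metaphase_length


def _cell_seeds(seed: int, n: int, tag: int) -> list:
    ss = np.random.SeedSequence([int(seed), int(tag)])
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def mean_foci_count(preset_name: str, n: int, seed: int) -> tuple[float, int]:
    """Mean resolvable-focus count over n fixed cells."""
    counts = []
    for s in _cell_seeds(seed, n, 1):
        image, _ = generate_cell_image(preset_name, s)
        counts.append(count_resolvable_foci(segment_foci(image)))
    return float(np.mean(counts)), n


@dataclass
class TimingCohort:
    durations: list = field(default_factory=list)
    metaphase_lengths: list = field(default_factory=list)
    nebd_errors: list = field(default_factory=list)      # vs planted truth, min
    anaphase_errors: list = field(default_factory=list)  # vs planted truth, min
    n_failed: int = 0

    @property
    def mean_duration(self) -> float:
        return float(np.mean(self.durations))


def timing_cohort(preset_name: str, n: int, seed: int) -> TimingCohort:
    """NEBD-to-anaphase durations (and metaphase lengths) over n movies."""
    out = TimingCohort()
    for s in _cell_seeds(seed, n, 2):
        movie, truth = generate_movie(preset_name, s)
        foci_sets = segment_movie(movie)
        centroid_sets = [f.centroids for f in foci_sets]
        try:
            t_nebd = detect_nebd(geminin_trace(movie), movie.times)
            ana = detect_anaphase(centroid_sets, movie.times)
        except AnalysisError:
            out.n_failed += 1
            continue
        out.durations.append(ana.time - t_nebd)
        out.nebd_errors.append(t_nebd - truth.t_nebd_true)
        out.anaphase_errors.append(ana.time - truth.t_anaphase_true)
        try:
            ml, _ = metaphase_length(foci_sets, movie.times, ana)
            out.metaphase_lengths.append(ml)
        except AnalysisError:
            pass
    return out


def error_rate_percent(preset_name: str, n: int, seed: int,
                       offset_min: float = 4.0) -> tuple[float, int]:
    """Percent of divisions flagged lagging or bridge at +offset minutes."""
    flags = []
    for s in _cell_seeds(seed, n, 3):
        movie, _ = generate_movie(preset_name, s)
        centroid_sets = [f.centroids for f in segment_movie(movie)]
        try:
            ana = detect_anaphase(centroid_sets, movie.times)
            call = score_errors(movie, ana, offset_min=offset_min)
        except AnalysisError:
            continue
        flags.append(call.any_error)
    return 100.0 * float(np.mean(flags)), len(flags)


def diplo_fraction_percent(preset_name: str, n: int, seed: int,
                           sex: str = "female") -> tuple[float, int]:
    """Percent of spreads classified euploid_diplo_tetraploid."""
    preset = get_preset(preset_name)
    hits = 0
    for s in _cell_seeds(seed, n, 4):
        image, _ = generate_spread_from_preset(preset, sex, s)
        call = classify_image(image, sex=sex)
        hits += call.ploidy_class == "euploid_diplo_tetraploid"
    return 100.0 * hits / n, n
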