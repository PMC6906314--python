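"""Parse sequentially-Markovian-coalescent output and summarize Ne.

MSMC2-style output tables carry scaled time boundaries and scaled
coalescence rates lambda per segment.  Conversion to biological units uses
``time_years = (scaled_time / mu_gen) * gen_time_years`` and
``Ne = 1 / (2 * mu_gen * lambda)``.  The long-term summary is the harmonic
mean of the per-segment Ne after trimming the poorly resolved first and
last segments.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .io_core import ConfigError, IntroscanError


@dataclass
class MsmcSegment:
    index: int
    left_scaled: float
    right_scaled: float
    lam: float


@dataclass
class NeTrajectory:
    """Piecewise-constant Ne over time in years (staircase)."""

    left_years: list
    right_years: list
    ne: list

    def __len__(self):
        return len(self.ne)


def mu_year_from_generation(mu_gen, gen_time_years) -> float:
    """Per-year mutation rate from the per-generation rate and generation time."""
    if mu_gen <= 0 or gen_time_years <= 0:
        raise ConfigError("mu_gen and gen_time_years must be > 0")
    return mu_gen / gen_time_years


def parse_msmc(path):
    """Read an MSMC2 output table into segments, validating contiguity."""
    segments = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if lineno == 1 and line.lower().startswith("time_index"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise IntroscanError(f"{path}:{lineno}: expected 4 tab-separated fields")
            try:
                idx = int(parts[0])
                left = float(parts[1])
                right = float(parts[2])
                lam = float(parts[3])
            except ValueError:
                raise IntroscanError(f"{path}:{lineno}: malformed numeric field") from None
            if not left < right:
                raise IntroscanError(f"{path}:{lineno}: left boundary not < right")
            segments.append(MsmcSegment(idx, left, right, lam))
    for prev, cur in zip(segments, segments[1:]):
        if not math.isclose(prev.right_scaled, cur.left_scaled, rel_tol=1e-9):
            raise IntroscanError(
                f"non-contiguous time boundaries at segment {cur.index}"
            )
    return segments


def convert_units(segments, mu_gen=0.8e-8, gen_time_years=4.0) -> NeTrajectory:
    """Scaled coalescence rates to years and diploid Ne."""
    if mu_gen <= 0:
        raise ConfigError("mu_gen must be > 0")
    left, right, ne = [], [], []
    for seg in segments:
        if seg.lam <= 0:
            raise IntroscanError(f"non-positive lambda in segment {seg.index}")
        left.append(seg.left_scaled / mu_gen * gen_time_years)
        right.append(seg.right_scaled / mu_gen * gen_time_years)
        ne.append(1.0 / (2.0 * mu_gen * seg.lam))
    return NeTrajectory(left, right, ne)


def harmonic_mean_ne(trajectory: NeTrajectory, drop_first=5, drop_last=5,
                     weight_by_duration=False) -> float:
    """Harmonic mean Ne over retained segments.

    Unweighted by default (n / sum(1/Ne)); with ``weight_by_duration`` each
    segment contributes proportionally to its time span (the last,
    unbounded segment is excluded in that mode).
    """
    stop = len(trajectory.ne) - drop_last
    vals = trajectory.ne[drop_first:stop]
    lefts = trajectory.left_years[drop_first:stop]
    rights = trajectory.right_years[drop_first:stop]
    if not vals:
        raise IntroscanError("no segments retained after trimming")
    if weight_by_duration:
        pairs = [
            (r - l, ne) for l, r, ne in zip(lefts, rights, vals) if math.isfinite(r)
        ]
        if not pairs:
            raise IntroscanError("no finite-duration segments retained")
        w_total = sum(w for w, _ in pairs)
        return w_total / sum(w / ne for w, ne in pairs)
    return len(vals) / sum(1.0 / ne for ne in vals)
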