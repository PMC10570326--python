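"""Success prediction for native-SAD phasing.

The predictor is deliberately simple: the ratio of symmetry-unique
reflections to anomalous scatterers in the asymmetric unit.  Experience
across many sulfur-SAD projects at long wavelength shows that phasing
typically succeeds when this ratio exceeds about 1000, so the inverse
question — what resolution does my crystal need to diffract to? — can be
answered by searching for the coarsest d_min at which the ratio clears the
threshold.

Conventions (documented because they matter):

* unique reflections are counted with Friedel mates merged and systematic
  absences excluded; pass ``merge_friedel=False`` for the unmerged dialect;
* anomalous scatterers are counted per asymmetric unit, making the ratio
  invariant under cell multiplicity (unique reflections are per-ASU too);
* only sulfur has a sequence-derived counter (Cys + Met); for any other
  scatterer set ``n_anom_per_asu`` directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .symmetry import SpaceGroup, UnitCell, count_unique

__all__ = [
    "DEFAULT_THRESHOLD",
    "CrystalContents",
    "FeasibilityReport",
    "count_sulfur_sites",
    "reflections_per_scatterer",
    "required_resolution",
    "project_outcome_summary",
]

#: Unique reflections per anomalous scatterer needed for routine success.
DEFAULT_THRESHOLD = 1000.0

_AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

# inverse search domain: a 0.01 A grid spanning all MX-relevant resolutions
_D_GRID_LO, _D_GRID_HI, _D_GRID_STEP = 0.5, 10.0, 0.01


def count_sulfur_sites(sequence: str, copies_per_asu: int = 1) -> int:
    """Number of sulfur atoms (Cys + Met) contributed by a protein sequence.

    ``copies_per_asu`` multiplies the per-chain count by the number of chain
    copies in the asymmetric unit.
    """
    if copies_per_asu < 1:
        raise ValueError("copies_per_asu must be >= 1")
    seq = sequence.upper()
    bad = [i for i, ch in enumerate(seq) if ch not in _AMINO_ACIDS]
    if bad:
        shown = ", ".join(f"{seq[i]!r}@{i}" for i in bad[:10])
        raise ValueError(
            f"sequence contains {len(bad)} non-amino-acid letter(s): {shown}"
        )
    return copies_per_asu * (seq.count("C") + seq.count("M"))


@dataclass(frozen=True)
class CrystalContents:
    """A crystal described by cell, space group and anomalous substructure."""

    cell: UnitCell
    sg: SpaceGroup
    n_anom_per_asu: int
    element: str = "S"

    def __post_init__(self) -> None:
        if self.n_anom_per_asu < 0:
            raise ValueError("n_anom_per_asu must be non-negative")


@dataclass(frozen=True)
class FeasibilityReport:
    """Outcome of the reflections-per-scatterer assessment."""

    n_unique: int
    n_anom: int
    ratio: float
    threshold: float
    verdict: bool  # True = favourable (ratio above threshold)
    d_min: Optional[float] = None
    d_required: Optional[float] = None
    unreachable: bool = False  # inverse search ran and found no resolution

    def to_dict(self) -> dict:
        out = {
            "n_unique": self.n_unique,
            "n_anom": self.n_anom,
            "ratio": self.ratio,
            "threshold": self.threshold,
            "verdict": "favourable" if self.verdict else "unfavourable",
            "d_min": self.d_min,
        }
        if self.unreachable:
            out["d_required"] = "unreachable"
        elif self.d_required is not None:
            out["d_required"] = self.d_required
        return out


def reflections_per_scatterer(
    contents: CrystalContents,
    d_min: float,
    threshold: float = DEFAULT_THRESHOLD,
    merge_friedel: bool = True,
) -> FeasibilityReport:
    """Unique reflections per anomalous scatterer at resolution ``d_min``."""
    if contents.n_anom_per_asu <= 0:
        raise ValueError(
            "the reflections-per-scatterer ratio is undefined without "
            "anomalous scatterers (n_anom_per_asu must be > 0)"
        )
    n_unique = count_unique(contents.cell, contents.sg, d_min,
                            merge_friedel=merge_friedel)
    ratio = n_unique / contents.n_anom_per_asu
    return FeasibilityReport(
        n_unique=n_unique,
        n_anom=contents.n_anom_per_asu,
        ratio=ratio,
        threshold=threshold,
        verdict=ratio > threshold,
        d_min=d_min,
    )


def required_resolution(
    contents: CrystalContents,
    threshold: float = DEFAULT_THRESHOLD,
    merge_friedel: bool = True,
) -> FeasibilityReport:
    """Coarsest d_min (0.01 A grid in [0.5, 10] A) with ratio above threshold.

    The ratio is non-increasing in d_min (nested resolution spheres), so the
    answer is found by bisection over the grid.  ``d_required`` is None when
    even 0.5 A does not reach the threshold.
    """
    if contents.n_anom_per_asu <= 0:
        raise ValueError(
            "required resolution is undefined without anomalous scatterers"
        )

    n_grid = round((_D_GRID_HI - _D_GRID_LO) / _D_GRID_STEP)  # grid points lo..hi

    def ratio_at(i: int) -> float:
        d = _D_GRID_LO + i * _D_GRID_STEP
        n = count_unique(contents.cell, contents.sg, d, merge_friedel=merge_friedel)
        return n / contents.n_anom_per_asu

    def passes(i: int) -> bool:
        return ratio_at(i) > threshold

    if not passes(0):
        return FeasibilityReport(
            n_unique=0, n_anom=contents.n_anom_per_asu, ratio=0.0,
            threshold=threshold, verdict=False, d_required=None,
            unreachable=True,
        )
    # invariant: passes(lo) is True; passes(hi) is False (or hi past the grid)
    lo, hi = 0, n_grid + 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if mid > n_grid or not passes(mid):
            hi = mid
        else:
            lo = mid
    d_req = round(_D_GRID_LO + lo * _D_GRID_STEP, 2)
    report = reflections_per_scatterer(contents, d_req, threshold=threshold,
                                       merge_friedel=merge_friedel)
    return FeasibilityReport(
        n_unique=report.n_unique,
        n_anom=report.n_anom,
        ratio=report.ratio,
        threshold=threshold,
        verdict=report.ratio > threshold,
        d_min=d_req,
        d_required=d_req,
    )


def project_outcome_summary(
    n_projects: int,
    n_solved: int,
    n_solved_below: int,
    n_failed_below: int,
    threshold: float = DEFAULT_THRESHOLD,
) -> dict:
    """Success/failure contingency summary for a set of phasing projects.

    Inputs are the total project count, the number solved, and how many of
    the solved/failed projects had a reflections-per-scatterer ratio below
    the threshold.  Returns counts and the derived percentages.
    """
    n_failed = n_projects - n_solved
    if n_failed < 0:
        raise ValueError("n_solved cannot exceed n_projects")
    if n_solved_below > n_solved or n_failed_below > n_failed:
        raise ValueError("below-threshold counts exceed their group totals")
    out = {
        "threshold": threshold,
        "n_projects": n_projects,
        "n_solved": n_solved,
        "n_failed": n_failed,
        "n_solved_below_threshold": n_solved_below,
        "n_failed_below_threshold": n_failed_below,
        "solved_percent": 100.0 * n_solved / n_projects if n_projects else 0.0,
        "solved_below_threshold_percent":
            100.0 * n_solved_below / n_solved if n_solved else 0.0,
        "failed_below_threshold_percent":
            100.0 * n_failed_below / n_failed if n_failed else 0.0,
    }
    return out
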