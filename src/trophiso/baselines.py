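"""Plant isotopic baselines per elevational bin.

Consumer trophic position is referenced against the δ¹⁵N of primary
producers.  Plants are pooled into broad elevational bins; a bin whose δ¹³C
distribution is bimodal (mixed C3 and C4/CAM photosynthetic pathways,
roughly −27 ‰ vs −13 ‰) can be split into two isotopic sources for the
two-baselines mixing model.  Baselines keep their raw sample values: the
Bayesian models treat baseline observations as data, not fixed constants.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    InsufficientBaselineError,
    ParseError,
    SchemaError,
    SplitError,
    ValidationError,
)
from .samples_io import DEFAULT_BINS, ElevationBin

__all__ = [
    "PlantSample",
    "BaselineDistribution",
    "BaselineMapping",
    "SiteModelSpec",
    "read_plants",
    "build_baseline",
    "build_baseline_union",
    "split_two_sources",
    "default_mapping",
    "map_site_to_baseline",
]

_ISO_BOUNDS = (-60.0, 60.0)

# Weak-bimodality heuristic: fraction of total δ13C sum-of-squares left
# within groups by the optimal split.  A clearly separated C3/C4 mixture
# leaves ~5%; a unimodal normal sample leaves ~35% (the 1-D two-means
# optimum explains ≈ 2/π of a normal's variance).
_BIMODALITY_WSS_RATIO = 0.25


@dataclass(frozen=True)
class PlantSample:
    """One plant specimen's δ¹³C/δ¹⁵N with its collection elevation."""

    plant_id: str
    elevation_m: float
    d13C: float
    d15N: float
    source: str | None = None  # optional manual C3/C4 label

    def __post_init__(self) -> None:
        for name in ("d13C", "d15N"):
            v = getattr(self, name)
            if not (math.isfinite(v) and _ISO_BOUNDS[0] <= v <= _ISO_BOUNDS[1]):
                raise ValidationError(
                    f"plant {self.plant_id!r}: {name} = {v} outside {_ISO_BOUNDS} ‰"
                )


@dataclass(frozen=True)
class BaselineDistribution:
    """δ¹⁵N (and δ¹³C) sample of primary producers for one bin / source."""

    bin_label: str
    source_label: str  # "single" | "source1" | "source2"
    d15N_values: tuple[float, ...]
    d13C_values: tuple[float, ...]

    @property
    def n(self) -> int:
        return len(self.d15N_values)

    @property
    def d15N_mean(self) -> float:
        return float(np.mean(self.d15N_values))

    @property
    def d15N_sd(self) -> float:
        return float(np.std(self.d15N_values, ddof=1))

    @property
    def d13C_mean(self) -> float:
        return float(np.mean(self.d13C_values))

    @property
    def d13C_sd(self) -> float:
        return float(np.std(self.d13C_values, ddof=1))

    def __post_init__(self) -> None:
        if len(self.d15N_values) != len(self.d13C_values):
            raise ValidationError(
                f"baseline {self.bin_label!r}: δ15N and δ13C value counts differ"
            )


def read_plants(path: str | Path) -> list[PlantSample]:
    """Read a plant CSV (plant_id, elevation_m, d13C, d15N[, source])."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=["", "NA"])
    required = ("plant_id", "elevation_m", "d13C", "d15N")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {', '.join(missing)}")
    plants, errors = [], []
    for idx, row in df.iterrows():
        rowno = int(idx) + 1
        try:
            plants.append(
                PlantSample(
                    plant_id=str(row["plant_id"]),
                    elevation_m=float(row["elevation_m"]),
                    d13C=float(row["d13C"]),
                    d15N=float(row["d15N"]),
                    source=(str(row["source"]) if "source" in df.columns
                            and not pd.isna(row["source"]) else None),
                )
            )
        except (TypeError, ValueError, ValidationError) as e:
            errors.append(f"row {rowno}: {e}")
    if errors:
        raise ParseError(f"{path.name}: {len(errors)} bad row(s):\n  " + "\n  ".join(errors))
    return plants


def build_baseline(
    plants: Sequence[PlantSample], bin: ElevationBin
) -> BaselineDistribution:
    """Single-source baseline from the plants falling inside *bin*."""
    inside = [p for p in plants if bin.contains(p.elevation_m)]
    if len(inside) < 2:
        raise InsufficientBaselineError(
            f"bin {bin.label!r}: {len(inside)} plant sample(s); at least 2 required"
        )
    return BaselineDistribution(
        bin_label=bin.label,
        source_label="single",
        d15N_values=tuple(p.d15N for p in inside),
        d13C_values=tuple(p.d13C for p in inside),
    )


def build_baseline_union(
    plants: Sequence[PlantSample], bins: Sequence[ElevationBin], label: str
) -> BaselineDistribution:
    """Baseline pooled over several bins (e.g. all plants above 4000 m)."""
    inside = [p for p in plants if any(b.contains(p.elevation_m) for b in bins)]
    if len(inside) < 2:
        raise InsufficientBaselineError(
            f"union baseline {label!r}: {len(inside)} plant sample(s); at least 2 required"
        )
    return BaselineDistribution(
        bin_label=label,
        source_label="single",
        d15N_values=tuple(p.d15N for p in inside),
        d13C_values=tuple(p.d13C for p in inside),
    )


def _best_split_index(x_sorted: np.ndarray) -> tuple[int, float]:
    """Optimal 1-D two-group partition of sorted values by within-group SS.

    Returns (k, wss) where the groups are x[:k] and x[k:].  For a 1-D sample
    the two-means optimum is always a contiguous split of the sorted values,
    so scanning the n−1 split points is an exact search.
    """
    n = x_sorted.size
    csum = np.cumsum(x_sorted)
    csum2 = np.cumsum(x_sorted**2)
    ks = np.arange(1, n)
    left_ss = csum2[ks - 1] - csum[ks - 1] ** 2 / ks
    right_n = n - ks
    right_sum = csum[-1] - csum[ks - 1]
    right_ss = (csum2[-1] - csum2[ks - 1]) - right_sum**2 / right_n
    wss = left_ss + right_ss
    k = int(np.argmin(wss))
    return int(ks[k]), float(wss[k])


def split_two_sources(
    baseline: BaselineDistribution,
) -> tuple[BaselineDistribution, BaselineDistribution]:
    """Partition a baseline into two δ¹³C sources (C3 vs C4/CAM).

    The split is the global optimum of the two-group within-sum-of-squares
    objective on δ¹³C.  source1 is the more ¹³C-depleted group (C3), source2
    the more enriched (C4/CAM).  Emits a warning when the δ¹³C sample shows
    no real bimodality.
    """
    if baseline.n < 4:
        raise SplitError(
            f"baseline {baseline.bin_label!r}: need at least 4 samples to split, "
            f"have {baseline.n}"
        )
    d13 = np.asarray(baseline.d13C_values, dtype=float)
    d15 = np.asarray(baseline.d15N_values, dtype=float)
    order = np.argsort(d13, kind="stable")
    k, wss = _best_split_index(d13[order])
    if k < 2 or baseline.n - k < 2:
        raise SplitError(
            f"baseline {baseline.bin_label!r}: optimal split leaves a group with "
            "fewer than 2 samples; fall back to a one-baseline model"
        )
    tss = float(np.sum((d13 - d13.mean()) ** 2))
    if tss == 0 or wss / tss > _BIMODALITY_WSS_RATIO:
        warnings.warn(
            f"baseline {baseline.bin_label!r}: δ13C distribution shows weak "
            "evidence of bimodality; the two-source split may be artificial",
            stacklevel=2,
        )
    lo, hi = order[:k], order[k:]
    mk = lambda idx, lab: BaselineDistribution(
        bin_label=baseline.bin_label,
        source_label=lab,
        d15N_values=tuple(d15[idx]),
        d13C_values=tuple(d13[idx]),
    )
    return mk(lo, "source1"), mk(hi, "source2")


# ---------------------------------------------------------------------------
# Site → baseline mapping

_MODEL_KINDS = ("oneBaseline", "twoBaselinesFull", "individualOneBaseline")


@dataclass(frozen=True)
class SiteModelSpec:
    """Which trophic-position model a site uses and on which plant bins."""

    model: str
    bins: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.model not in _MODEL_KINDS:
            raise ConfigurationError(
                f"unknown model kind {self.model!r}; expected one of {_MODEL_KINDS}"
            )
        if not self.bins:
            raise ConfigurationError("a site mapping must name at least one bin")


@dataclass(frozen=True)
class BaselineMapping:
    """site_id → model kind + plant bin(s); every site mapped exactly once."""

    sites: Mapping[str, SiteModelSpec]

    def spec_for(self, site_id: str) -> SiteModelSpec:
        try:
            return self.sites[site_id]
        except KeyError:
            raise ConfigurationError(
                f"site {site_id!r} is not covered by the baseline mapping"
            ) from None


def default_mapping() -> BaselineMapping:
    """The study's mapping: low site one-baseline, mid site two-source mixing,
    high sites one-baseline on all plants above 4000 m, summit individual."""
    gt4000 = ("4000-5000", ">5000")
    return BaselineMapping(
        sites={
            "Site 1": SiteModelSpec("oneBaseline", ("2000-3000",)),
            "Site 2": SiteModelSpec("twoBaselinesFull", ("3000-4000",)),
            "Site 3": SiteModelSpec("oneBaseline", gt4000),
            "Site 4": SiteModelSpec("oneBaseline", gt4000),
            "Site 5": SiteModelSpec("oneBaseline", gt4000),
            "Site 6": SiteModelSpec("oneBaseline", gt4000),
            "Site 7": SiteModelSpec("individualOneBaseline", gt4000),
        }
    )


def map_site_to_baseline(
    site_id: str,
    mapping: BaselineMapping,
    plants: Sequence[PlantSample],
    bins: Sequence[ElevationBin] = DEFAULT_BINS,
) -> tuple[str, tuple[BaselineDistribution, ...]]:
    """Resolve a site to its model kind and concrete baseline distribution(s).

    For ``twoBaselinesFull`` the named bin's baseline is split into two δ¹³C
    sources (a manual ``source`` label on the plants takes precedence over
    the automatic split).
    """
    spec = mapping.spec_for(site_id)
    by_label = {b.label: b for b in bins}
    for lab in spec.bins:
        if lab not in by_label:
            raise ConfigurationError(
                f"site {site_id!r}: mapping names unknown bin {lab!r}"
            )
    chosen = [by_label[lab] for lab in spec.bins]
    if spec.model == "twoBaselinesFull":
        if len(chosen) != 1:
            raise ConfigurationError(
                f"site {site_id!r}: a two-baselines model maps to exactly one bin"
            )
        base = build_baseline(plants, chosen[0])
        manual = [p for p in plants if chosen[0].contains(p.elevation_m)]
        labels = {p.source for p in manual}
        if None not in labels and len(labels) == 2:
            lab1, lab2 = sorted(labels)  # type: ignore[type-var]
            g1 = [p for p in manual if p.source == lab1]
            g2 = [p for p in manual if p.source == lab2]
            if min(len(g1), len(g2)) < 2:
                raise SplitError(
                    f"site {site_id!r}: manual source groups need >= 2 plants each"
                )
            # order by mean d13C so source1 is the C3 (depleted) group
            if np.mean([p.d13C for p in g1]) > np.mean([p.d13C for p in g2]):
                g1, g2 = g2, g1
            mk = lambda g, lab: BaselineDistribution(
                bin_label=chosen[0].label, source_label=lab,
                d15N_values=tuple(p.d15N for p in g),
                d13C_values=tuple(p.d13C for p in g),
            )
            return spec.model, (mk(g1, "source1"), mk(g2, "source2"))
        return spec.model, split_two_sources(base)
    if len(chosen) == 1:
        base = build_baseline(plants, chosen[0])
    else:
        base = build_baseline_union(plants, chosen, label="+".join(spec.bins))
    return spec.model, (base,)
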