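"""Seeded generators for synthetic consumer and plant isotope datasets.

The defaults emulate the statistical structure of a liver stable-isotope
survey of *Phyllotis vaccarum* along a ~2400–6700 m Andean elevational
gradient: seven collection sites with the per-site sample sizes, means and
SDs of the study (one singleton summit animal), a C:N distribution of
3.8 ± 0.5 truncated to a plausible liver range, a weak negative C:N–δ¹³C
coupling within sites, and plant baselines per elevational bin whose
3000–4000 m bin is a bimodal C3 vs C4/CAM δ¹³C mixture.  Consumers can also
be generated at known trophic position for parameter-recovery studies.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .baselines import BaselineDistribution
from .errors import ValidationError
from .trophic_models import TDFSet

__all__ = [
    "SiteSpec",
    "MixtureComponent",
    "BaselineSpec",
    "KnownTPSpec",
    "DEFAULT_SITE_SPECS",
    "DEFAULT_PLANT_SPECS",
    "simulate_sites",
    "simulate_plants",
    "simulate_consumers_known_tp",
    "make_fixture_bundle",
]


@dataclass(frozen=True)
class SiteSpec:
    """Per-site consumer generator: n and (mean, SD) per variable."""

    site_id: str
    elevation_m: float
    n: int
    d13C_mean: float
    d13C_sd: float
    d15N_mean: float
    d15N_sd: float
    d34S_mean: float
    d34S_sd: float
    cn_mean: float
    cn_sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"site {self.site_id!r}: n must be >= 1")
        for name in ("d13C_sd", "d15N_sd", "d34S_sd", "cn_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"site {self.site_id!r}: {name} must be >= 0")


#: Default survey: seven sites spanning 2370–6739 m, 41 animals in all.
#: Bulk δ¹³C, δ¹⁵N, δ³⁴S and C:N moments follow the study's site table.
DEFAULT_SITE_SPECS: tuple[SiteSpec, ...] = (
    SiteSpec("Site 1", 2370, 8, -18.3, 2.2, 19.2, 3.6, -1.6, 0.8, 4.2, 0.8),
    SiteSpec("Site 2", 3240, 8, -16.2, 1.8, 10.1, 0.9, -1.5, 0.7, 4.0, 0.6),
    SiteSpec("Site 3", 4150, 4, -22.6, 0.4, 7.6, 0.8, 0.5, 1.3, 3.4, 0.1),
    SiteSpec("Site 4", 4360, 8, -22.8, 0.5, 7.6, 1.0, 1.6, 0.5, 3.8, 0.3),
    SiteSpec("Site 5", 4620, 5, -23.3, 0.2, 7.1, 0.1, 1.3, 0.1, 3.7, 0.2),
    SiteSpec("Site 6", 5070, 7, -22.0, 1.1, 10.2, 2.1, 1.0, 0.9, 3.8, 0.4),
    SiteSpec("Site 7", 6739, 1, -22.0, 0.0, 7.0, 0.0, 2.0, 0.0, 3.3, 0.0),
)


@dataclass(frozen=True)
class MixtureComponent:
    weight: float
    d13C_mean: float
    d13C_sd: float
    d15N_mean: float
    d15N_sd: float


@dataclass(frozen=True)
class BaselineSpec:
    """Plant generator for one elevational bin; 2 components = C3/C4 mixture."""

    bin_label: str
    elevation_range: tuple[float, float]
    n: int
    components: tuple[MixtureComponent, ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValidationError(f"bin {self.bin_label!r}: needs >= 1 component")
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"bin {self.bin_label!r}: component weights sum to {total}, not 1"
            )


#: Default plant baselines.  δ¹³C ≈ −26 ‰ for C3, ≈ −13 ‰ for C4/CAM; the
#: mid-elevation bin is an even C3 / C4-CAM mixture; plant δ¹⁵N is similar
#: at low and mid elevations (≈ 5–6.5 ‰) and ¹⁵N-depleted above 4000 m
#: (≈ 2 ‰), the pattern that anchors herbivore TP ≈ 2 at high elevation.
DEFAULT_PLANT_SPECS: tuple[BaselineSpec, ...] = (
    BaselineSpec("2000-3000", (2000, 3000), 24,
                 (MixtureComponent(1.0, -20.0, 5.0, 5.0, 1.5),)),
    BaselineSpec("3000-4000", (3000, 4000), 30,
                 (MixtureComponent(0.5, -26.0, 1.5, 5.0, 1.5),
                  MixtureComponent(0.5, -13.0, 1.5, 6.5, 1.5))),
    BaselineSpec("4000-5000", (4000, 5000), 20,
                 (MixtureComponent(1.0, -26.0, 1.5, 2.0, 1.5),)),
    BaselineSpec(">5000", (5000, 5400), 8,
                 (MixtureComponent(1.0, -26.5, 1.0, 1.0, 1.0),)),
)


def _truncated_corr_pair(
    rng: np.random.Generator,
    n: int,
    cn_mean: float,
    cn_sd: float,
    d13c_mean: float,
    d13c_sd: float,
    corr: float,
    cn_range: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """(C:N, δ¹³C) pairs with correlation *corr*, C:N rejection-truncated."""
    lo, hi = cn_range
    out_cn = np.empty(n)
    out_c = np.empty(n)
    filled = 0
    while filled < n:
        need = n - filled
        z1 = rng.standard_normal(need)
        z2 = corr * z1 + math.sqrt(max(1.0 - corr**2, 0.0)) * rng.standard_normal(need)
        cn = cn_mean + cn_sd * z1
        keep = (cn >= lo) & (cn <= hi) if cn_sd > 0 else np.ones(need, bool)
        k = int(keep.sum())
        out_cn[filled : filled + k] = cn[keep]
        out_c[filled : filled + k] = d13c_mean + d13c_sd * z2[keep]
        filled += k
    return out_cn, out_c


def simulate_sites(
    specs: Sequence[SiteSpec] = DEFAULT_SITE_SPECS,
    seed: int = 0,
    cn_range: tuple[float, float] = (3.0, 6.0),
    cn_d13c_corr: float = -0.3,
) -> pd.DataFrame:
    """Per-individual consumer table in the CSV schema read by samples_io.

    Variables are independent Normals per site except the (C:N, bulk δ¹³C)
    pair, drawn jointly with the configured negative correlation; C:N is
    rejection-truncated to *cn_range*.  %C and %N columns are emitted
    consistently with the drawn C:N.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    rows = []
    for spec in specs:
        cn, d13c = _truncated_corr_pair(
            rng, spec.n, spec.cn_mean, spec.cn_sd, spec.d13C_mean, spec.d13C_sd,
            cn_d13c_corr, cn_range,
        )
        d15n = spec.d15N_mean + spec.d15N_sd * rng.standard_normal(spec.n)
        d34s = spec.d34S_mean + spec.d34S_sd * rng.standard_normal(spec.n)
        pn = rng.uniform(8.0, 12.0, spec.n)  # liver %N; %C follows from C:N
        for i in range(spec.n):
            rows.append(
                {
                    "sample_id": f"{spec.site_id.replace(' ', '')}-{i + 1:02d}",
                    "site_id": spec.site_id,
                    "elevation_m": spec.elevation_m,
                    "d13C": round(float(d13c[i]), 4),
                    "d15N": round(float(d15n[i]), 4),
                    "d34S": round(float(d34s[i]), 4),
                    "percent_N": round(float(pn[i]), 4),
                    "percent_C": round(float(pn[i] * cn[i]), 4),
                }
            )
    return pd.DataFrame(rows)


def simulate_plants(
    specs: Sequence[BaselineSpec] = DEFAULT_PLANT_SPECS,
    seed: int = 0,
) -> pd.DataFrame:
    """Plant table (plant_id, elevation_m, d13C, d15N, component) drawn from
    per-bin mixture specs; component labels are retained for oracle checks."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    rows = []
    for spec in specs:
        weights = np.array([c.weight for c in spec.components])
        comp_idx = rng.choice(len(spec.components), size=spec.n, p=weights)
        lo, hi = spec.elevation_range
        elev = rng.uniform(lo, min(hi, lo + 1e6), spec.n)
        for i in range(spec.n):
            c = spec.components[int(comp_idx[i])]
            rows.append(
                {
                    "plant_id": f"P-{spec.bin_label}-{i + 1:02d}",
                    "elevation_m": round(float(elev[i]), 1),
                    "d13C": round(float(rng.normal(c.d13C_mean, c.d13C_sd)), 4),
                    "d15N": round(float(rng.normal(c.d15N_mean, c.d15N_sd)), 4),
                    "component": int(comp_idx[i]),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class KnownTPSpec:
    """Generator spec for consumers at known trophic position."""

    tp_true: float
    sigma_consumer: float
    n_consumers: int
    baseline: BaselineDistribution
    baseline2: BaselineDistribution | None = None
    alpha_true: float | None = None
    tdf: TDFSet = field(default_factory=TDFSet)
    lambda_: float = 1.0

    def __post_init__(self) -> None:
        if self.tp_true < 1:
            raise ValidationError("tp_true must be >= 1")
        if self.alpha_true is not None and not 0 <= self.alpha_true <= 1:
            raise ValidationError("alpha_true must be in [0, 1]")
        if self.baseline2 is not None and self.alpha_true is None:
            raise ValidationError("two-source spec requires alpha_true")
        if self.n_consumers < 1:
            raise ValidationError("n_consumers must be >= 1")
        if self.sigma_consumer < 0:
            raise ValidationError("sigma_consumer must be >= 0")


def simulate_consumers_known_tp(
    spec: KnownTPSpec, seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Consumers generated by inverting the TP equation:
    δ¹⁵N = baseline mean + Δ¹⁵N·(TP − λ) + noise (δ¹³C analogously for the
    two-source case).  Returns (consumer table, truth record)."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    n = spec.n_consumers
    step = spec.tp_true - spec.lambda_
    if spec.baseline2 is None:
        mu_n = spec.baseline.d15N_mean + spec.tdf.d15N_mean * step
        mu_c = spec.baseline.d13C_mean + spec.tdf.d13C_mean * step
    else:
        a = float(spec.alpha_true)  # type: ignore[arg-type]
        mu_n = (a * spec.baseline.d15N_mean
                + (1 - a) * spec.baseline2.d15N_mean
                + spec.tdf.d15N_mean * step)
        mu_c = (a * spec.baseline.d13C_mean
                + (1 - a) * spec.baseline2.d13C_mean
                + spec.tdf.d13C_mean * step)
    d15n = mu_n + spec.sigma_consumer * rng.standard_normal(n)
    d13c = mu_c + spec.sigma_consumer * rng.standard_normal(n)
    df = pd.DataFrame(
        {
            "sample_id": [f"sim-{i + 1:03d}" for i in range(n)],
            "site_id": "sim",
            "elevation_m": 4000.0,
            "d13C": np.round(d13c, 6),
            "d15N": np.round(d15n, 6),
            "d34S": 0.0,
            "cn_ratio": 3.8,
        }
    )
    truth = {
        "tp_true": spec.tp_true,
        "alpha_true": spec.alpha_true,
        "sigma_consumer": spec.sigma_consumer,
        "n_consumers": n,
        "lambda": spec.lambda_,
        "seed": seed,
    }
    return df, truth


def make_fixture_bundle(outdir: str | Path, seed: int = 42) -> dict[str, Path]:
    """Write a complete small dataset + run configuration.

    The bundle (consumers.csv, plants.csv, config.yaml, truth.json) runs the
    full pipeline end to end; its MCMC settings are shortened to fixture
    scale (3 chains × 4000 iterations).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    consumers = simulate_sites(seed=seed)
    plants = simulate_plants(seed=seed + 1)
    cpath = outdir / "consumers.csv"
    ppath = outdir / "plants.csv"
    consumers.to_csv(cpath, index=False)
    plants.drop(columns=["component"]).to_csv(ppath, index=False)
    config = {
        "consumers": "consumers.csv",
        "plants": "plants.csv",
        "seed": int(seed),
        "lipid_coefficients": "liver-ethanol",
        "n_perm": 999,
        "mapping": {
            "Site 1": {"model": "oneBaseline", "bins": ["2000-3000"]},
            "Site 2": {"model": "twoBaselinesFull", "bins": ["3000-4000"]},
            "Site 3": {"model": "oneBaseline", "bins": ["4000-5000", ">5000"]},
            "Site 4": {"model": "oneBaseline", "bins": ["4000-5000", ">5000"]},
            "Site 5": {"model": "oneBaseline", "bins": ["4000-5000", ">5000"]},
            "Site 6": {"model": "oneBaseline", "bins": ["4000-5000", ">5000"]},
            "Site 7": {"model": "individualOneBaseline",
                       "bins": ["4000-5000", ">5000"]},
        },
        "mcmc": {"population": {"n_chains": 3, "n_adapt": 500, "n_iter": 4000,
                                "n_burnin": 500, "thin": 5},
                 "individual": {"n_chains": 8, "n_adapt": 1000, "n_iter": 600,
                                "n_burnin": 0, "thin": 8, "n_walkers": 8}},
    }
    import yaml

    cfg_path = outdir / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump({"seed": int(seed), "site_specs": [s.site_id for s in
                                                     DEFAULT_SITE_SPECS]}, fh,
                  indent=2)
    return {"consumers": cpath, "plants": ppath, "config": cfg_path,
            "truth": truth_path}
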