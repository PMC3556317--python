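"""Mid-parent and high-parent heterosis of replicated trait measurements.

MPH = 100 * (F1 - MP) / MP with MP the parental average; HPH uses the
better parent instead.  Significance comes from t-tests: a composite-
variance t for MPH (F1 mean against the mid-parent composite) and a
Welch two-sample t for HPH (F1 against the best parent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TraitMeasurements",
    "HeterosisResult",
    "compute_heterosis",
    "test_heterosis",
    "heterosis_table",
    "read_traits",
    "write_traits",
]


@dataclass
class TraitMeasurements:
    """Replicate values of one trait for P1, P2 and F1."""

    name: str
    units: str
    values: Mapping[str, Sequence[float]]  # genotype -> replicate values
    larger_is_better: bool = True

    def __post_init__(self) -> None:
        missing = {"P1", "P2", "F1"} - set(self.values)
        if missing:
            raise ValueError(f"trait {self.name!r}: missing genotypes {sorted(missing)}")
        clean = {}
        for geno, vals in self.values.items():
            arr = np.asarray(vals, dtype=float)
            if arr.size < 2:
                raise ValueError(
                    f"trait {self.name!r}, genotype {geno}: need >= 2 replicates"
                )
            if not np.isfinite(arr).all():
                raise ValueError(f"trait {self.name!r}, genotype {geno}: non-finite values")
            clean[geno] = arr
        self.values = clean

    def mean(self, geno: str) -> float:
        return float(np.mean(self.values[geno]))

    def sd(self, geno: str) -> float:
        return float(np.std(self.values[geno], ddof=1))

    def n(self, geno: str) -> int:
        return int(np.asarray(self.values[geno]).size)

    @property
    def best_parent(self) -> str:
        p1, p2 = self.mean("P1"), self.mean("P2")
        if self.larger_is_better:
            return "P1" if p1 >= p2 else "P2"
        return "P1" if p1 <= p2 else "P2"


@dataclass
class HeterosisResult:
    trait: str
    units: str
    means: dict
    sds: dict
    mph: float  # percent, 2 d.p.
    hph: float  # percent, 2 d.p.
    p_mph: float = field(default=np.nan)
    p_hph: float = field(default=np.nan)

    @property
    def stars_mph(self) -> str:
        return _stars(self.p_mph)

    @property
    def stars_hph(self) -> str:
        return _stars(self.p_hph)


def _stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def compute_heterosis(t: TraitMeasurements) -> HeterosisResult:
    """MPH/HPH percentages (2 d.p.) from the genotype means."""
    means = {g: t.mean(g) for g in ("P1", "P2", "F1")}
    sds = {g: t.sd(g) for g in ("P1", "P2", "F1")}
    mp = (means["P1"] + means["P2"]) / 2.0
    hp = means[t.best_parent]
    if mp == 0:
        raise ValueError(f"trait {t.name!r}: mid-parent mean is zero")
    if hp == 0:
        raise ValueError(f"trait {t.name!r}: high-parent mean is zero")
    mph = round(100.0 * (means["F1"] - mp) / mp, 2)
    hph = round(100.0 * (means["F1"] - hp) / hp, 2)
    return HeterosisResult(trait=t.name, units=t.units, means=means, sds=sds, mph=mph, hph=hph)


def _welch(mean1, var1, n1, mean2, var2, n2) -> float:
    """Two-sided Welch t-test p-value from summary statistics."""
    se2 = var1 / n1 + var2 / n2
    diff = mean1 - mean2
    if se2 == 0:
        return 1.0 if diff == 0 else 0.0
    tstat = diff / np.sqrt(se2)
    num = se2**2
    den = (var1 / n1) ** 2 / (n1 - 1) + (var2 / n2) ** 2 / (n2 - 1)
    df = num / den if den > 0 else n1 + n2 - 2
    return float(2.0 * stats.t.sf(abs(tstat), df))


def test_heterosis(t: TraitMeasurements) -> tuple[float, float]:
    """(p_MPH, p_HPH), two-sided.

    MPH: t = (F1bar - MPbar) / sqrt(s2_F1/n_F1 + (s2_P1/n_P1 + s2_P2/n_P2)/4)
    with Satterthwaite degrees of freedom on the composite variance.
    HPH: Welch t of F1 against the best parent.  Zero variance everywhere
    resolves to p = 1 on zero difference, p = 0 otherwise.
    """
    m = {g: t.mean(g) for g in ("P1", "P2", "F1")}
    v = {g: np.var(t.values[g], ddof=1) for g in ("P1", "P2", "F1")}
    n = {g: t.n(g) for g in ("P1", "P2", "F1")}

    diff = m["F1"] - (m["P1"] + m["P2"]) / 2.0
    comps = np.array([v["F1"] / n["F1"], v["P1"] / n["P1"] / 4.0, v["P2"] / n["P2"] / 4.0])
    se2 = comps.sum()
    if se2 == 0:
        p_mph = 1.0 if diff == 0 else 0.0
    else:
        tstat = diff / np.sqrt(se2)
        dfs = np.array([n["F1"] - 1, n["P1"] - 1, n["P2"] - 1], dtype=float)
        df = se2**2 / (comps**2 / dfs).sum()
        p_mph = float(2.0 * stats.t.sf(abs(tstat), df))

    bp = t.best_parent
    p_hph = _welch(m["F1"], v["F1"], n["F1"], m[bp], v[bp], n[bp])
    return p_mph, p_hph


def heterosis_table(traits: Sequence[TraitMeasurements]) -> pd.DataFrame:
    """Full per-trait heterosis report (one row per trait)."""
    rows = []
    for t in traits:
        res = compute_heterosis(t)
        res.p_mph, res.p_hph = test_heterosis(t)
        rows.append(
            {
                "trait": res.trait,
                "units": res.units,
                "mean_P1": res.means["P1"],
                "mean_P2": res.means["P2"],
                "mean_F1": res.means["F1"],
                "sd_P1": res.sds["P1"],
                "sd_P2": res.sds["P2"],
                "sd_F1": res.sds["F1"],
                "MPH_pct": res.mph,
                "HPH_pct": res.hph,
                "p_MPH": res.p_mph,
                "p_HPH": res.p_hph,
                "stars_MPH": res.stars_mph,
                "stars_HPH": res.stars_hph,
            }
        )
    return pd.DataFrame(rows).set_index("trait")


def write_traits(traits: Sequence[TraitMeasurements], path: str | Path) -> None:
    """Long-format traits.tsv: trait, units, genotype, replicate, value."""
    rows = []
    for t in traits:
        for geno in ("P1", "P2", "F1"):
            for i, val in enumerate(t.values[geno], start=1):
                rows.append(
                    {
                        "trait": t.name,
                        "units": t.units,
                        "genotype": geno,
                        "replicate": i,
                        "value": val,
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_traits(path: str | Path) -> list[TraitMeasurements]:
    df = pd.read_csv(path, sep="\t")
    df["units"] = df.get("units", "").fillna("") if "units" in df else ""
    out = []
    for name, grp in df.groupby("trait", sort=False):
        units = str(grp["units"].iloc[0]) if "units" in grp else ""
        vals = {g: sub["value"].to_numpy() for g, sub in grp.groupby("genotype")}
        out.append(TraitMeasurements(name=name, units=units, values=vals))
    return out
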