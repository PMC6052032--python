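"""Per-part, per-phenotype JND tables and detectability / advantage summaries.

A flower part is scored against the mean leafy background for every colour
vision phenotype.  Parts above 1 JND are detectable; between 1 and 2 JND
detection is marginal; a phenotype has an *advantage* on a part when its
chromatic distance exceeds that of every dichromat phenotype by at least
1 JND.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError
from .photoreceptor import default_phenotypes
from .rnl import Illuminant, catch_vector, chromatic_jnd, luminance_contrast, receptor_contrast
from .spectra import Spectrum, SpectrumSet

DETECTABLE_JND = 1.0
MARGINAL_JND = 2.0


def jnd_table(
    flowers: SpectrumSet,
    background: Spectrum,
    phenotypes=None,
    illuminant: Illuminant | None = None,
) -> pd.DataFrame:
    """Chromatic and achromatic contrast of every flower part for every
    phenotype, against the mean leaf background.

    Returns a tidy frame with columns ``species, part_label, phenotype,
    phenotype_class, delta_s, delta_lum``.
    """
    if background is None:
        raise DataError("a mean leaf background is required")
    if phenotypes is None:
        phenotypes = default_phenotypes()
    if illuminant is None:
        illuminant = Illuminant.flat(background.wavelengths)
    bg_catches = {p.name: catch_vector(background, p, illuminant) for p in phenotypes}
    rows = []
    for s in flowers:
        for p in phenotypes:
            ct = catch_vector(s, p, illuminant)
            df = receptor_contrast(ct, bg_catches[p.name])
            rows.append(
                {
                    "species": s.meta.get("species"),
                    "part_label": s.meta.get("part_label"),
                    "phenotype": p.name,
                    "phenotype_class": p.phenotype_class,
                    "delta_s": chromatic_jnd(df, p),
                    "delta_lum": luminance_contrast(ct, bg_catches[p.name], p),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ConspicuitySummary:
    """Detectability counts and class means derived from a JND table."""

    n_parts: int
    n_species: int
    mean_delta_s: dict                      # class -> pooled-cell mean
    mean_delta_s_parts_first: dict          # class -> mean of per-part means
    per_phenotype: pd.DataFrame             # phenotype-level counts
    not_detectable_any_dichromat: int       # parts <1 JND for >=1 dichromat
    not_detectable_all_dichromats: int      # parts <1 JND for every dichromat
    marginal_any_dichromat: int             # parts in [1,2) for >=1 dichromat
    marginal_all_dichromats: int
    boundary_parts: list = field(default_factory=list)  # cells with delta_s == 1

    def to_dict(self) -> dict:
        d = {
            "n_parts": self.n_parts,
            "n_species": self.n_species,
            "mean_delta_s": self.mean_delta_s,
            "mean_delta_s_parts_first": self.mean_delta_s_parts_first,
            "not_detectable_any_dichromat": self.not_detectable_any_dichromat,
            "not_detectable_all_dichromats": self.not_detectable_all_dichromats,
            "marginal_any_dichromat": self.marginal_any_dichromat,
            "marginal_all_dichromats": self.marginal_all_dichromats,
            "boundary_parts": self.boundary_parts,
            "per_phenotype": self.per_phenotype.to_dict(orient="records"),
        }
        return d


def detectability_summary(table: pd.DataFrame) -> ConspicuitySummary:
    """Apply the 1 / 2 JND thresholds and aggregate by phenotype class.

    A part is *not detectable* for a phenotype when ``delta_s < 1`` and
    *marginal* when ``1 <= delta_s < 2``.  Because "for dichromats" can be
    read per-phenotype or pooled, both the any-dichromat and the
    all-dichromat counts are reported, alongside the full per-phenotype
    breakdown.  Cells at exactly 1 JND count as detectable and are flagged.
    """
    t = table.copy()
    t["part_key"] = t["species"].astype(str) + "||" + t["part_label"].astype(str)
    per_rows = []
    for ph, sub in t.groupby("phenotype", sort=True):
        per_rows.append(
            {
                "phenotype": ph,
                "phenotype_class": sub["phenotype_class"].iloc[0],
                "n_parts": sub["part_key"].nunique(),
                "n_not_detectable": int((sub["delta_s"] < DETECTABLE_JND).sum()),
                "n_marginal": int(
                    (
                        (sub["delta_s"] >= DETECTABLE_JND)
                        & (sub["delta_s"] < MARGINAL_JND)
                    ).sum()
                ),
                "mean_delta_s": float(sub["delta_s"].mean()),
            }
        )
    per = pd.DataFrame(per_rows)

    di = t[t["phenotype_class"] == "dichromat"]
    nd = di.assign(flag=di["delta_s"] < DETECTABLE_JND).groupby("part_key")["flag"]
    mg_mask = (di["delta_s"] >= DETECTABLE_JND) & (di["delta_s"] < MARGINAL_JND)
    mg = di.assign(flag=mg_mask).groupby("part_key")["flag"]

    mean_by_class = t.groupby("phenotype_class")["delta_s"].mean().to_dict()
    parts_first = (
        t.groupby(["phenotype_class", "part_key"])["delta_s"]
        .mean()
        .groupby("phenotype_class")
        .mean()
        .to_dict()
    )
    boundary = t.loc[
        np.isclose(t["delta_s"], DETECTABLE_JND), ["part_key", "phenotype"]
    ].apply(tuple, axis=1).tolist()

    return ConspicuitySummary(
        n_parts=int(t["part_key"].nunique()),
        n_species=int(t["species"].nunique()),
        mean_delta_s={k: float(v) for k, v in mean_by_class.items()},
        mean_delta_s_parts_first={k: float(v) for k, v in parts_first.items()},
        per_phenotype=per,
        not_detectable_any_dichromat=int(nd.any().sum()) if len(di) else 0,
        not_detectable_all_dichromats=int(nd.all().sum()) if len(di) else 0,
        marginal_any_dichromat=int(mg.any().sum()) if len(di) else 0,
        marginal_all_dichromats=int(mg.all().sum()) if len(di) else 0,
        boundary_parts=boundary,
    )


def advantage_summary(table: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Detection advantages of each trichromat phenotype over all dichromats.

    A part is advantaged for trichromat phenotype T when
    ``delta_s(T) - max over dichromat phenotypes of delta_s >= threshold``
    (boundary inclusive).  A species is advantaged under the default
    any-part rule when at least one of its parts is; the stricter all-parts
    count is reported alongside.
    """
    t = table.copy()
    t["part_key"] = t["species"].astype(str) + "||" + t["part_label"].astype(str)
    di = t[t["phenotype_class"] == "dichromat"]
    if di.empty:
        raise DataError("advantage summary needs dichromat rows for reference")
    di_max = di.groupby("part_key")["delta_s"].max()
    rows = []
    for ph, sub in t[t["phenotype_class"] == "trichromat"].groupby("phenotype", sort=True):
        sub = sub.set_index("part_key")
        margin = sub["delta_s"] - di_max.reindex(sub.index)
        adv = margin >= threshold
        species_of = sub["species"]
        by_species = adv.groupby(species_of)
        rows.append(
            {
                "phenotype": ph,
                "threshold": threshold,
                "n_parts": int(len(sub)),
                "n_parts_advantaged": int(adv.sum()),
                "n_species": int(species_of.nunique()),
                "n_species_advantaged_any_part": int(by_species.any().sum()),
                "n_species_advantaged_all_parts": int(by_species.all().sum()),
            }
        )
    return pd.DataFrame(rows)
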