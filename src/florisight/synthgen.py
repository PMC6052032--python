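"""Seeded generators for synthetic reflectance spectra and behaviour tables.

The spectral generator emulates a tropical-dry-forest dataset: green foliage
(a chlorophyll reflectance bump near 550 nm over a dark floor, with the
start of the near-infrared rise above ~690 nm), red flowers (a logistic
red-edge step), white flowers (flat, bright) and white-green flowers (bright
leaf-shaped spectra, chromatically close to foliage).  The red flower /
green leaf pairing is deliberately parameterised so that the difference
lives almost entirely in the long-wavelength region where the 532, 543 and
561 nm pigments separate — the phenomenon the discrimination analysis is
about.  These are parametric curves, not measured spectra.

The behaviour generator draws NB2 counts with a trichromat log-rate-ratio,
offsets and Gaussian random intercepts — exactly the structure the count
models assume — plus a phenotype roster following the study population's
phenotype distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .count_models import SMALL_PATCH_SPECIES, phenotype_class_of
from .exceptions import ConfigError
from .spectra import Spectrum, SpectrumSet

# ---------------------------------------------------------------------------
# spectra


DEFAULT_LEAF = {
    "floor": 0.04,        # dark base reflectance
    "bump_amp": 0.13,     # green reflectance bump height
    "bump_center": 552.0,  # nm
    "bump_width": 38.0,   # Gaussian sigma, nm
    "nir_rise": 0.35,     # asymptote of the near-infrared rise
    "nir_mid": 704.0,     # logistic midpoint, nm (mostly beyond the window)
    "nir_steep": 6.0,
}

DEFAULT_FLOWER_CLASSES = {
    # logistic step up at the red edge: dark below, bright above.  The floor
    # is tuned so the S-vs-L/M balance of the flower falls inside the leaf
    # population's spread (near-metameric for dichromats) while the step
    # beyond 580 nm separates cleanly on the trichromat red-green axis.
    "red_edge": {"edge": 583.0, "steepness": 12.0, "floor": 0.06, "ceiling": 0.65},
    # flat, bright
    "white": {"level": 0.70},
    # bright leaf-shaped spectrum with a small flat (white) admixture:
    # chromatically inside the foliage cloud, separable mainly by lightness
    "white_green": {"flat": 0.04, "scale": 0.75},
}

#: Species-level parameter jitter: log-normal sigma for relative keys,
#: Gaussian sd in nm for keys listed in ``_ABSOLUTE_KEYS``.  Leaves are
#: deliberately diverse (shade/sun, young/old, pale/saturated foliage) so the
#: background is genuinely heterogeneous in chromaticity, not just intensity.
LEAF_JITTER = {
    "floor": 0.50,
    "bump_amp": 0.35,
    "bump_center": 8.0,
    "bump_width": 0.10,
    "nir_rise": 0.20,
    "nir_mid": 4.0,
    "nir_steep": 0.10,
}

FLOWER_JITTER = {
    "red_edge": {"edge": 4.0, "steepness": 0.10, "floor": 0.08, "ceiling": 0.10},
    "white": {"level": 0.10},
    "white_green": {"flat": 0.10, "scale": 0.10},
}

#: Within-part, replicate-to-replicate chromatic jitter (same units as above):
#: individual flowers of one part differ strongly in pigmentation and
#: maturity, so replicate chromaticity scatters across the leaf population's
#: chromatic spread in the dimensions where flower and foliage overlap.
REPLICATE_JITTER = {
    "red_edge": {"edge": 6.0, "floor": 0.90, "ceiling": 0.10},
    "white": {"level": 0.04},
    "white_green": {"flat": 0.80, "scale": 0.05},
}

#: Within-species leaf variation (relative to the across-species jitter) and
#: the extra foliage-shape diversity of white-green flower replicates.
LEAF_REPLICATE_SCALE = 0.25
WHITE_GREEN_SHAPE_SCALE = 1.3

_ABSOLUTE_KEYS = {"edge", "bump_center", "nir_mid"}


@dataclass
class SpectraScenario:
    """Parameters of one synthetic spectral dataset."""

    n_leaf_species: int = 28
    replicates: int = 5
    parts_per_class: dict = field(
        default_factory=lambda: {"red_edge": 3, "white": 2, "white_green": 2}
    )
    leaf: dict = field(default_factory=lambda: dict(DEFAULT_LEAF))
    flower_classes: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_FLOWER_CLASSES.items()}
    )
    noise_sd: float = 0.04          # multiplicative (log-normal) replicate noise
    diversity: float = 1.0          # scales all species-level parameter jitter
    replicate_jitter_scale: float = 1.0  # scales all within-part chromatic jitter
    step: float = 1.0               # grid step, nm
    seed: int = 0

    def grid(self):
        n = int(round(300.0 / self.step))
        return 400.0 + self.step * np.arange(n + 1)


def _logistic(x, mid, steep):
    return 1.0 / (1.0 + np.exp(-(x - mid) / steep))


def leaf_curve(grid, params) -> np.ndarray:
    p = params
    return (
        p["floor"]
        + p["bump_amp"] * np.exp(-0.5 * ((grid - p["bump_center"]) / p["bump_width"]) ** 2)
        + p["nir_rise"] * _logistic(grid, p["nir_mid"], p["nir_steep"])
    )


def flower_curve(grid, cls, params, leaf_params) -> np.ndarray:
    if cls == "red_edge":
        return params["floor"] + (params["ceiling"] - params["floor"]) * _logistic(
            grid, params["edge"], params["steepness"]
        )
    if cls == "white":
        return np.full_like(grid, params["level"])
    if cls == "white_green":
        shape = leaf_curve(grid, leaf_params)
        shape = shape / shape.max()
        flat = min(params["flat"], 1.0)
        return params["scale"] * (flat + (1.0 - flat) * shape)
    raise ConfigError(f"unknown flower class {cls!r}")


def generate_spectra(sc: SpectraScenario, seed=None) -> SpectrumSet:
    """Generate leaf and flower reflectance spectra per the scenario.

    Leaves: ``n_leaf_species`` species, upper and lower surfaces (the lower
    surface a brighter variant), one spectrum each.  Flowers: for each class,
    ``parts_per_class[class]`` parts with ``replicates`` replicate spectra.
    Species-level jitter perturbs curve parameters once per species/part;
    replicate noise is multiplicative log-normal.  All reflectances are
    clipped to [0, 1].  Bit-reproducible for a given seed.
    """
    rng = np.random.default_rng(sc.seed if seed is None else seed)
    grid = sc.grid()
    out = SpectrumSet()

    def jittered(params, sds, scale=1.0):
        j = {}
        for k, v in params.items():
            sd = sds.get(k, 0.0) * scale
            if sd == 0.0:
                j[k] = v
            elif k in _ABSOLUTE_KEYS:
                j[k] = v + rng.normal(0.0, sd)
            else:
                j[k] = v * np.exp(rng.normal(0.0, sd))
        return j

    for i in range(sc.n_leaf_species):
        lp = jittered(sc.leaf, LEAF_JITTER, sc.diversity)
        for surface, bright in (("upper", 1.0), ("lower", 1.35)):
            for r in range(sc.replicates):
                rp = jittered(
                    lp,
                    LEAF_JITTER,
                    sc.diversity * LEAF_REPLICATE_SCALE * sc.replicate_jitter_scale,
                )
                vals = leaf_curve(grid, rp) * bright
                vals = vals * np.exp(rng.normal(0.0, sc.noise_sd))
                out.spectra.append(
                    Spectrum(
                        grid.copy(),
                        np.clip(vals, 0.0, 1.0),
                        {
                            "species": f"leafsp{i + 1:02d}",
                            "item_kind": "leaf",
                            "part_label": "leaf",
                            "surface": surface,
                            "replicate_id": f"r{r + 1}",
                        },
                    )
                )

    for cls, n_parts in sc.parts_per_class.items():
        base_params = sc.flower_classes[cls]
        sp_sds = FLOWER_JITTER.get(cls, {})
        rep_sds = REPLICATE_JITTER.get(cls, {})
        for j in range(n_parts):
            sp = f"{cls}_sp{j + 1:02d}"
            params = jittered(base_params, sp_sds, sc.diversity)
            for r in range(sc.replicates):
                rp = jittered(params, rep_sds, sc.replicate_jitter_scale)
                # white-green flowers are leaf metamers: each replicate gets
                # its own foliage-like shape, as variable as the leaves
                leaf_params = (
                    jittered(
                        sc.leaf,
                        LEAF_JITTER,
                        sc.diversity
                        * WHITE_GREEN_SHAPE_SCALE
                        * sc.replicate_jitter_scale,
                    )
                    if cls == "white_green"
                    else sc.leaf
                )
                vals = flower_curve(grid, cls, rp, leaf_params)
                vals = vals * np.exp(rng.normal(0.0, sc.noise_sd))
                out.spectra.append(
                    Spectrum(
                        grid.copy(),
                        np.clip(vals, 0.0, 1.0),
                        {
                            "species": sp,
                            "item_kind": "flower",
                            "part_label": f"{cls}_part{j + 1}",
                            "surface": "n/a",
                            "replicate_id": f"r{r + 1}",
                        },
                    )
                )
    out.note(
        f"synthetic spectra: {sc.n_leaf_species} leaf species x 2 surfaces, "
        f"{sum(sc.parts_per_class.values())} flower parts x {sc.replicates} replicates"
    )
    return out


def red_edge_scenario(**overrides) -> SpectraScenario:
    """Red-flower scenario: red-edge flowers only, against diverse foliage.

    Emulates the situation of a red tubular flower: near-metameric with
    foliage for dichromats, strongly separated on the trichromat red-green
    axis.
    """
    kwargs = {"parts_per_class": {"red_edge": 6}}
    kwargs.update(overrides)
    return SpectraScenario(**kwargs)


def white_flower_scenario(**overrides) -> SpectraScenario:
    """White-green-flower scenario: bright leaf-shaped flowers only.

    Chromatically inside the foliage cloud for every phenotype but much
    brighter, so discrimination succeeds only through the lightness channel.
    """
    kwargs = {"parts_per_class": {"white_green": 6}}
    kwargs.update(overrides)
    return SpectraScenario(**kwargs)


# ---------------------------------------------------------------------------
# behaviour


#: Phenotype counts in the study population (sex ratios within phenotype).
POPULATION_PHENOTYPES = {
    "532": (11, 0),      # (n, n_female)
    "543": (17, 2),
    "561": (45, 19),
    "532/543": (6, 6),
    "532/561": (24, 24),
    "543/561": (7, 7),
}


@dataclass
class BehaviorScenario:
    """Parameters of one synthetic behavioural dataset.

    Scan counts: ``log mu = beta0_scan + beta_phenotype * trichromat +
    b_individual + b_cycle + log(total scans)``.  FLPV counts:
    ``log mu = beta0_flpv + beta_phenotype * trichromat + b_group +
    log(group hours)``.  Both NB2 with dispersion ``theta``.
    """

    n_individuals: int = 83
    n_groups: int = 4
    n_cycles: int = 13
    phenotype_counts: dict = field(
        default_factory=lambda: dict(POPULATION_PHENOTYPES)
    )
    beta0_scan: float = -5.5        # log baseline scan rate (~0.4% of scans)
    beta0_flpv: float = -5.75       # log baseline FLPV rate per hour
    beta_phenotype: float = 0.6882  # trichromat log rate ratio (FLPV analysis)
    beta_phenotype_scan: float = 0.3153  # trichromat log rate ratio (scan analysis)
    theta: float = 1.5              # NB2 dispersion
    sigma_individual: float = 0.3
    sigma_cycle: float = 0.2
    sigma_group: float = 0.3
    mean_total_scans: float = 50.0  # scans per individual per cycle
    hours_range: tuple = (380.0, 520.0)  # observation hours per group
    p_low_presence: float = 0.06    # fraction of sporadically-seen individuals
    n_distractor_species: int = 3   # large-patch species mixed into FLPV records
    seed: int = 0


def generate_behavior(sc: BehaviorScenario, seed=None) -> dict:
    """Generate roster, scan table, FLPV records and group hours.

    Returns a dict with keys ``roster``, ``scans``, ``flpv``, ``hours``.
    The roster draws phenotypes (and sex within phenotype) from the study
    population's distribution; scan and FLPV counts follow the NB2 mixed
    models described on the scenario.  Bit-reproducible for a given seed.
    """
    rng = np.random.default_rng(sc.seed if seed is None else seed)

    names = list(sc.phenotype_counts)
    weights = np.array([sc.phenotype_counts[n][0] for n in names], dtype=float)
    probs = weights / weights.sum()
    p_female = {
        n: (sc.phenotype_counts[n][1] / sc.phenotype_counts[n][0])
        for n in names
    }

    roster_rows = []
    for i in range(sc.n_individuals):
        ph = names[rng.choice(len(names), p=probs)]
        sex = "F" if rng.random() < p_female[ph] else "M"
        roster_rows.append(
            {
                "individual_id": f"ind{i + 1:03d}",
                "sex": sex,
                "group": f"G{rng.integers(sc.n_groups) + 1}",
                "phenotype": ph,
                "phenotype_class": phenotype_class_of(ph),
            }
        )
    roster = pd.DataFrame(roster_rows)
    tri = (roster["phenotype_class"] == "trichromat").to_numpy(float)

    b_ind = rng.normal(0.0, sc.sigma_individual, sc.n_individuals)
    b_cyc = rng.normal(0.0, sc.sigma_cycle, sc.n_cycles)
    group_ids = sorted(roster["group"].unique())
    b_grp = {g: rng.normal(0.0, sc.sigma_group) for g in group_ids}

    # presence: most individuals seen nearly every cycle, a few sporadically
    low = rng.random(sc.n_individuals) < sc.p_low_presence
    p_present = np.where(low, 0.35, 0.95)

    scan_rows = []
    for i, row in roster.iterrows():
        for c in range(sc.n_cycles):
            if rng.random() > p_present[i]:
                continue
            total = int(max(1, rng.poisson(sc.mean_total_scans)))
            mu = np.exp(
                sc.beta0_scan
                + sc.beta_phenotype_scan * tri[i]
                + b_ind[i]
                + b_cyc[c]
                + np.log(total)
            )
            y = _rnb2(rng, mu, sc.theta)
            scan_rows.append(
                {
                    "individual_id": row["individual_id"],
                    "phenotype": row["phenotype"],
                    "phenotype_class": row["phenotype_class"],
                    "sex": row["sex"],
                    "group": row["group"],
                    "cycle_id": f"c{c + 1:02d}",
                    "flower_scans": int(min(y, total)),
                    "total_scans": total,
                }
            )
    scans = pd.DataFrame(scan_rows)

    hours = pd.DataFrame(
        {
            "group": group_ids,
            "hours": rng.uniform(*sc.hours_range, len(group_ids)),
        }
    )
    hours_of = dict(zip(hours["group"], hours["hours"]))

    small = list(SMALL_PATCH_SPECIES)
    distractors = ["Luehea speciosa", "Diphysa americana", "Gliricidia sepium"][
        : sc.n_distractor_species
    ]
    flpv_rows = []
    for i, row in roster.iterrows():
        g = row["group"]
        mu = np.exp(
            sc.beta0_flpv
            + sc.beta_phenotype * tri[i]
            + b_grp[g]
            + np.log(hours_of[g])
        )
        y = _rnb2(rng, mu, sc.theta)
        for _ in range(int(y)):
            flpv_rows.append(
                {
                    "individual_id": row["individual_id"],
                    "group": g,
                    "species": small[rng.integers(len(small))],
                }
            )
        # large-patch visits that the small-patch filter must drop
        for _ in range(int(rng.poisson(0.8 * max(mu, 0.05)))):
            flpv_rows.append(
                {
                    "individual_id": row["individual_id"],
                    "group": g,
                    "species": distractors[rng.integers(len(distractors))]
                    if distractors
                    else small[0],
                }
            )
    flpv = pd.DataFrame(flpv_rows, columns=["individual_id", "group", "species"])

    return {"roster": roster, "scans": scans, "flpv": flpv, "hours": hours}


def _rnb2(rng, mu, theta):
    """One NB2 draw via the gamma-Poisson mixture."""
    lam = rng.gamma(shape=theta, scale=mu / theta)
    return int(rng.poisson(lam))


def scenario_to_dict(sc) -> dict:
    return asdict(sc)
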