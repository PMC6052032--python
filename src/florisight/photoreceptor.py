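"""Visual-pigment templates and colour-vision phenotypes.

Capuchins carry three L/M opsin alleles with peak sensitivities at 532, 543
and 561 nm on an X-linked locus, plus an autosomal S pigment.  Males and
homozygous females are dichromats (S + one L/M class); heterozygous females
are trichromats (S + two L/M classes), giving six phenotypes in all.

Pigment absorbance curves are generated from ``lambda_max`` with the Lamb
exponential template (default) or the Govardovskii A1 template, both
peak-normalised.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

from .exceptions import ConfigError

#: Lamb (1995) template constants: S(x) = N / (e^{a(A-x)} + e^{b(B-x)} + e^{c(C-x)} + D)
#: with x = lambda_max / lambda.
LAMB_CONSTANTS = {
    "a": 70.0,
    "A": 0.880,
    "b": 28.5,
    "B": 0.924,
    "c": -14.1,
    "C": 1.104,
    "D": 0.655,
}

#: The three capuchin L/M allele peak sensitivities (nm).
LM_ALLELES = (532.0, 543.0, 561.0)

#: Conventional capuchin S-cone peak (nm); configurable per phenotype.
DEFAULT_S_LAMBDA_MAX = 430.0


@dataclass
class PigmentTemplate:
    """Peak-normalised relative absorbance of one visual pigment on a grid."""

    lambda_max: float
    grid: np.ndarray
    sensitivity: np.ndarray
    family: str = "lamb"

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.sensitivity = np.asarray(self.sensitivity, dtype=float)

    def __call__(self, wavelengths):
        return np.interp(np.asarray(wavelengths, float), self.grid, self.sensitivity)


def _lamb_raw(lambda_max, wavelengths, constants):
    c = constants
    x = lambda_max / np.asarray(wavelengths, dtype=float)
    denom = (
        np.exp(c["a"] * (c["A"] - x))
        + np.exp(c["b"] * (c["B"] - x))
        + np.exp(c["c"] * (c["C"] - x))
        + c["D"]
    )
    return 1.0 / denom


def lamb_template(lambda_max, grid, constants=None) -> PigmentTemplate:
    """Absorbance template from the Lamb exponential closed form.

    ``S(lambda) = N / (e^{a(A-x)} + e^{b(B-x)} + e^{c(C-x)} + D)`` with
    ``x = lambda_max/lambda``; ``N`` normalises the peak on ``grid`` to 1.
    """
    grid = np.asarray(grid, dtype=float)
    if not 400.0 <= lambda_max <= 700.0:
        raise ConfigError(f"lambda_max {lambda_max} nm outside 400-700 nm")
    if lambda_max < grid[0] or lambda_max > grid[-1]:
        warnings.warn(
            f"lambda_max {lambda_max} nm lies outside the grid span "
            f"{grid[0]:g}-{grid[-1]:g} nm; the template peak is clipped",
            stacklevel=2,
        )
    cst = dict(LAMB_CONSTANTS)
    cst.update(constants or {})
    raw = _lamb_raw(lambda_max, grid, cst)
    return PigmentTemplate(lambda_max, grid, raw / raw.max(), family="lamb")


def _govardovskii_raw(lambda_max, wavelengths, beta_band=True):
    wl = np.asarray(wavelengths, dtype=float)
    x = lambda_max / wl
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    if not beta_band:
        return alpha
    lmb = 189.0 + 0.315 * lambda_max
    b = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((wl - lmb) / b) ** 2))
    return alpha + beta


def govardovskii_template(lambda_max, grid, beta_band=True) -> PigmentTemplate:
    """Govardovskii et al. A1 pigment nomogram (alpha band + optional beta band)."""
    grid = np.asarray(grid, dtype=float)
    if not 400.0 <= lambda_max <= 700.0:
        raise ConfigError(f"lambda_max {lambda_max} nm outside 400-700 nm")
    raw = _govardovskii_raw(lambda_max, grid, beta_band=beta_band)
    return PigmentTemplate(lambda_max, grid, raw / raw.max(), family="govardovskii")


TEMPLATE_FAMILIES = {"lamb": lamb_template, "govardovskii": govardovskii_template}


def make_template(lambda_max, grid, family="lamb", **kwargs) -> PigmentTemplate:
    try:
        fn = TEMPLATE_FAMILIES[family]
    except KeyError:
        raise ConfigError(f"unknown template family {family!r}") from None
    return fn(lambda_max, grid, **kwargs)


# ---------------------------------------------------------------------------
# phenotypes


@dataclass
class Phenotype:
    """A colour-vision phenotype: cone peak sensitivities plus noise settings.

    Parameters
    ----------
    name : str
        Label such as ``"532"`` (dichromat) or ``"532/561"`` (trichromat).
    lm_lambda_max : tuple of float
        One (dichromat) or two distinct (trichromat) L/M peaks in nm.
    s_lambda_max : float
        S-cone peak, default 430 nm.
    nu : float, optional
        Noise of a single receptor cell.  If omitted it is scaled so the most
        abundant cone class has Weber fraction 0.05.
    eta : tuple of float, optional
        Relative receptor densities, S first then L/M classes in ascending
        lambda_max order.  Default S : L/M = 1 : 16, the L/M share split
        equally between the two classes of a trichromat.
    omega_lum : float
        Weber fraction of the achromatic (luminance) channel, default 0.05.
    template_family : str
        ``"lamb"`` or ``"govardovskii"``.
    """

    name: str
    lm_lambda_max: tuple
    s_lambda_max: float = DEFAULT_S_LAMBDA_MAX
    nu: float | None = None
    eta: tuple | None = None
    omega_lum: float = 0.05
    template_family: str = "lamb"
    template_kwargs: dict = field(default_factory=dict)

    def __post_init__(self):
        lm = tuple(float(v) for v in np.atleast_1d(self.lm_lambda_max))
        if not 1 <= len(lm) <= 2:
            raise ConfigError(f"{self.name!r}: need 1 or 2 L/M peaks, got {len(lm)}")
        if len(lm) == 2 and lm[0] == lm[1]:
            raise ConfigError(
                f"{self.name!r}: a trichromat needs two distinct L/M peaks, "
                f"got {lm[0]:g} twice"
            )
        self.lm_lambda_max = tuple(sorted(lm))

    # -- structure ------------------------------------------------------
    @property
    def is_trichromat(self) -> bool:
        return len(self.lm_lambda_max) == 2

    @property
    def phenotype_class(self) -> str:
        return "trichromat" if self.is_trichromat else "dichromat"

    @property
    def n_receptors(self) -> int:
        return 1 + len(self.lm_lambda_max)

    @property
    def lambda_maxes(self) -> tuple:
        """All receptor peaks, S first then ascending L/M."""
        return (self.s_lambda_max,) + self.lm_lambda_max

    # -- noise ----------------------------------------------------------
    def densities(self) -> np.ndarray:
        """Relative receptor densities eta_i, ordered as ``lambda_maxes``."""
        if self.eta is not None:
            eta = np.asarray(self.eta, dtype=float)
            if eta.size != self.n_receptors:
                raise ConfigError(
                    f"{self.name!r}: eta has {eta.size} entries for "
                    f"{self.n_receptors} receptors"
                )
            return eta
        if self.is_trichromat:
            return np.array([1.0, 8.0, 8.0])
        return np.array([1.0, 16.0])

    def weber_fractions(self) -> np.ndarray:
        """Per-channel Weber fractions omega_i = nu / sqrt(eta_i)."""
        eta = self.densities()
        nu = self.nu if self.nu is not None else 0.05 * np.sqrt(eta.max())
        return nu / np.sqrt(eta)

    # -- construction ---------------------------------------------------
    @classmethod
    def from_name(cls, name: str, **kwargs) -> "Phenotype":
        """Build a phenotype from a label like ``"561"`` or ``"532/561"``."""
        try:
            peaks = tuple(float(tok) for tok in str(name).split("/"))
        except ValueError:
            raise ConfigError(f"cannot parse phenotype name {name!r}") from None
        return cls(name=str(name), lm_lambda_max=peaks, **kwargs)


def phenotype_sensitivities(p: Phenotype, grid) -> list:
    """Ordered receptor templates for a phenotype: [S, M, (L)]."""
    return [
        make_template(lm, grid, family=p.template_family, **p.template_kwargs)
        for lm in p.lambda_maxes
    ]


def luminance_sensitivity(p: Phenotype, grid) -> PigmentTemplate:
    """Achromatic-channel sensitivity: the equal-weight sum of the L/M
    templates, peak-normalised.  For a dichromat this is simply its single
    L/M template."""
    templates = [
        make_template(lm, grid, family=p.template_family, **p.template_kwargs)
        for lm in p.lm_lambda_max
    ]
    total = np.sum([t.sensitivity for t in templates], axis=0)
    grid = np.asarray(grid, dtype=float)
    lam_peak = float(grid[np.argmax(total)])
    return PigmentTemplate(lam_peak, grid, total / total.max(), family="luminance")


# ---------------------------------------------------------------------------
# registry


def default_phenotypes(**overrides) -> list:
    """The six phenotypes found in the study population."""
    names = ["532", "543", "561", "532/543", "532/561", "543/561"]
    return [Phenotype.from_name(n, **overrides) for n in names]


def load_phenotypes(path=None) -> list:
    """Load a phenotype registry from YAML.

    The registry maps names to ``{lm_lambda_max: [..], s_lambda_max: ..,
    noise: {nu, eta, omega_lum}, template_family: ..}``.  Without ``path``
    the packaged registry (the six study phenotypes) is used.
    """
    if path is None:
        ref = importlib.resources.files("florisight").joinpath("data/phenotypes.yaml")
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "phenotypes" not in doc:
        raise ConfigError("phenotype registry must have a top-level 'phenotypes' map")
    out = []
    for name, entry in doc["phenotypes"].items():
        entry = entry or {}
        noise = entry.get("noise", {}) or {}
        kwargs = {}
        if "lm_lambda_max" in entry:
            kwargs["lm_lambda_max"] = tuple(entry["lm_lambda_max"])
        if "s_lambda_max" in entry:
            kwargs["s_lambda_max"] = float(entry["s_lambda_max"])
        if "nu" in noise and noise["nu"] is not None:
            kwargs["nu"] = float(noise["nu"])
        if "eta" in noise and noise["eta"] is not None:
            kwargs["eta"] = tuple(noise["eta"])
        if "omega_lum" in noise and noise["omega_lum"] is not None:
            kwargs["omega_lum"] = float(noise["omega_lum"])
        if "template_family" in entry:
            kwargs["template_family"] = entry["template_family"]
        if "lm_lambda_max" in kwargs:
            lm = kwargs.pop("lm_lambda_max")
            out.append(Phenotype(name=str(name), lm_lambda_max=lm, **kwargs))
        else:
            out.append(Phenotype.from_name(str(name), **kwargs))
    return out
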