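"""Leave-one-out SVM discriminability of flowers against the leafy background.

Each flower replicate is plotted in the chromaticity space available to a
phenotype (one opponent axis for a dichromat, two for a trichromat,
optionally a lightness axis) together with every individual leaf spectrum.
A support vector machine is then asked, leaving each flower replicate out in
turn, whether it can tell that replicate from the leaves.  A part counts as
correctly categorised when the majority of its held-out replicates are.

Leaves are never held out: the question is flower detectability against the
background, not leaf classification.  Because leaves vastly outnumber the
~5 replicates of any one part, the SVM uses inverse-frequency class weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .exceptions import DataError
from .photoreceptor import Phenotype, default_phenotypes
from .rnl import Illuminant, catch_vector, chromaticity_coords
from .spectra import SpectrumSet


@dataclass
class SVMConfig:
    """Fixed SVM instrument settings.

    kernel: ``"rbf"`` (default) or ``"linear"``; C: regularisation; gamma:
    ``"median"`` sets the RBF bandwidth by the median heuristic on the
    standardised training rows, or pass a float.
    """

    kernel: str = "rbf"
    C: float = 1.0
    gamma: object = "median"
    class_weight: object = "balanced"


@dataclass
class DiscriminationResult:
    phenotype: str
    part_label: str
    include_lightness: bool
    n_flower_samples: int
    n_correct_loo: int
    flagged: bool = False  # single-replicate part: LOO is degenerate

    @property
    def majority_correct(self) -> bool:
        return self.n_correct_loo > self.n_flower_samples / 2


def build_features(
    flower_samples: SpectrumSet,
    leaves: SpectrumSet,
    p: Phenotype,
    include_lightness: bool = False,
    illuminant: Illuminant | None = None,
):
    """Chromaticity feature matrix for flower replicates + all leaves.

    Returns ``(X, y, parts)`` where ``y`` is 1 for flower rows and 0 for
    leaf rows and ``parts`` carries the part label of each flower row
    (``None`` for leaves).  Standardisation is *not* applied here — it is
    fitted on the training rows of each leave-one-out fold.
    """
    if len(leaves) < 2:
        raise DataError("need at least 2 leaf samples for a background class")
    grid = leaves.common_grid()
    if illuminant is None:
        illuminant = Illuminant.flat(grid)
    rows, labels, parts = [], [], []
    for s in flower_samples:
        c = catch_vector(s, p, illuminant)
        rows.append(chromaticity_coords(c, p, include_lightness))
        labels.append(1)
        parts.append(s.meta.get("part_label"))
    for s in leaves:
        c = catch_vector(s, p, illuminant)
        rows.append(chromaticity_coords(c, p, include_lightness))
        labels.append(0)
        parts.append(None)
    return np.asarray(rows), np.asarray(labels), parts


def _median_gamma(X):
    n = X.shape[0]
    if n > 400:  # subsample for the heuristic; deterministic stride
        X = X[:: int(np.ceil(n / 400))]
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    vals = d2[np.triu_indices_from(d2, k=1)]
    vals = vals[vals > 0]
    if vals.size == 0:
        return 1.0
    med = np.sqrt(np.median(vals))
    return 1.0 / (2.0 * med**2)


def _make_svc(Xtr, config: SVMConfig) -> SVC:
    gamma = config.gamma
    if config.kernel == "rbf" and gamma == "median":
        gamma = _median_gamma(Xtr)
    elif gamma == "median":
        gamma = "scale"
    return SVC(kernel=config.kernel, C=config.C, gamma=gamma,
               class_weight=config.class_weight)


def loo_classify(
    features: np.ndarray,
    labels: np.ndarray,
    config: SVMConfig | None = None,
    phenotype: str = "",
    part_label: str = "",
    include_lightness: bool = False,
) -> DiscriminationResult:
    """Leave-one-flower-out classification.

    For each flower row in turn the SVM is trained on all remaining rows
    (every leaf plus the other flower replicates) and predicts the held-out
    replicate; ``n_correct_loo`` counts correct flower predictions.  With a
    single flower replicate the held-out fold has no flower training rows at
    all, so the result is flagged as degenerate.
    """
    config = config or SVMConfig()
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    flower_idx = np.flatnonzero(labels == 1)
    if flower_idx.size == 0 or np.unique(labels).size < 2:
        raise DataError("need both flower and leaf rows")
    flagged = flower_idx.size == 1
    n_correct = 0
    for i in flower_idx:
        mask = np.ones(len(labels), dtype=bool)
        mask[i] = False
        Xtr, ytr = features[mask], labels[mask]
        if np.unique(ytr).size < 2:
            # no flower rows left to train on: predict leaf, i.e. incorrect
            continue
        if np.ptp(Xtr, axis=0).max() == 0.0 and np.all(Xtr[0] == features[i]):
            # zero-information geometry: classes are identical point masses,
            # so the held-out sample defaults to the background class
            continue
        scaler = StandardScaler().fit(Xtr)
        Xtr_s = scaler.transform(Xtr)
        clf = _make_svc(Xtr_s, config).fit(Xtr_s, ytr)
        pred = clf.predict(scaler.transform(features[[i]]))[0]
        n_correct += int(pred == 1)
    return DiscriminationResult(
        phenotype=phenotype,
        part_label=part_label,
        include_lightness=include_lightness,
        n_flower_samples=int(flower_idx.size),
        n_correct_loo=n_correct,
        flagged=flagged,
    )


def discrimination_report(
    flowers: SpectrumSet,
    leaves: SpectrumSet,
    phenotypes=None,
    lightness_settings=(False, True),
    config: SVMConfig | None = None,
    illuminant: Illuminant | None = None,
) -> pd.DataFrame:
    """Full part x phenotype x lightness discrimination table.

    ``flowers`` must contain individual replicate spectra (not part means);
    parts are taken from ``meta["part_label"]`` within species.
    """
    if phenotypes is None:
        phenotypes = default_phenotypes()
    config = config or SVMConfig()
    part_keys = []
    for s in flowers:
        k = (s.meta.get("species"), s.meta.get("part_label"))
        if k not in part_keys:
            part_keys.append(k)
    rows = []
    for p in phenotypes:
        for include_lightness in lightness_settings:
            X_all, y_all, parts_all = build_features(
                flowers, leaves, p, include_lightness, illuminant
            )
            leaf_rows = y_all == 0
            species_all = [s.meta.get("species") for s in flowers] + [None] * int(
                leaf_rows.sum()
            )
            for species, part in part_keys:
                part_rows = np.array(
                    [
                        (sp == species and pl == part)
                        for sp, pl in zip(species_all, parts_all)
                    ]
                )
                keep = part_rows | leaf_rows
                X = X_all[keep]
                y = np.where(part_rows[keep], 1, 0)
                res = loo_classify(
                    X, y, config,
                    phenotype=p.name, part_label=str(part),
                    include_lightness=include_lightness,
                )
                rows.append(
                    {
                        "species": species,
                        "part_label": part,
                        "phenotype": p.name,
                        "phenotype_class": p.phenotype_class,
                        "include_lightness": include_lightness,
                        "n_flower_samples": res.n_flower_samples,
                        "n_correct_loo": res.n_correct_loo,
                        "majority_correct": res.majority_correct,
                        "flagged": res.flagged,
                    }
                )
    return pd.DataFrame(rows)
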