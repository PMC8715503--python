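"""Statistical classification of perturbed residues and molecular-viewer
script generation for binding-site mapping.

Residues are classified against the whole-protein CSP mean and standard
deviation (population SD):

* outlier     CSP > mean + 4·SD   (likely artifacts; excluded from highlighting)
* high        mean + 2·SD < CSP <= mean + 4·SD   (red spheres, scale 1.0)
* moderate    mean + 1·SD <= CSP <= mean + 2·SD  (pink spheres, scale 0.7)
* background  everything else     (gray cartoon only)

A degenerate profile with SD = 0 (e.g. an unperturbed protein) maps every
residue to background rather than flagging the whole chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from sklearn.base import BaseEstimator

from .errors import InsufficientDataError

CATEGORIES = ("outlier", "high", "moderate", "background")


@dataclass(frozen=True)
class ResidueClassification:
    """Per-residue perturbation categories plus the statistics that defined them."""

    categories: dict[int, str]
    mean_csp: float
    sd_csp: float

    def residues(self, category: str) -> tuple[int, ...]:
        return tuple(sorted(r for r, c in self.categories.items() if c == category))


class PerturbationClassifier(BaseEstimator):
    """Threshold residues of a CSP profile by whole-protein mean and SD.

    Parameters
    ----------
    recompute_after_outliers : bool, default False
        When True, the mean and SD used for the high/moderate cuts are
        recomputed after removing >4·SD outliers.  The default keeps the
        single-pass statistics (computed once over all residues), since the
        mapping protocol lists the computation before the outlier removal
        and never mentions recomputation.

    Attributes
    ----------
    mean_ : float
        Mean CSP actually used for the high/moderate thresholds.
    sd_ : float
        Population standard deviation used for the thresholds.
    categories_ : dict[int, str]
        Category per residue of the fitted profile.
    """

    def __init__(self, recompute_after_outliers: bool = False):
        self.recompute_after_outliers = recompute_after_outliers

    @staticmethod
    def _split(values: np.ndarray, mean: float, sd: float) -> np.ndarray:
        cats = np.full(values.shape, "background", dtype=object)
        if sd == 0:
            return cats
        cats[(values >= mean + sd) & (values <= mean + 2 * sd)] = "moderate"
        cats[(values > mean + 2 * sd) & (values <= mean + 4 * sd)] = "high"
        cats[values > mean + 4 * sd] = "outlier"
        return cats

    def fit(self, X: Mapping[int, float], y=None) -> "PerturbationClassifier":
        """Compute statistics and categories for the profile ``X``."""
        if len(X) < 2:
            raise InsufficientDataError(
                "at least 2 residues are required to define mean and SD"
            )
        residues = sorted(X)
        values = np.array([float(X[r]) for r in residues])
        if np.any(values < 0) or not np.isfinite(values).all():
            raise ValueError("CSP values must be finite and nonnegative")
        mean = float(values.mean())
        sd = float(values.std())  # population SD: descriptive over the full set
        # a numerically flat profile (constant CSPs) has SD 0 up to rounding
        if sd <= 1e-12 * max(abs(mean), np.finfo(float).tiny):
            sd = 0.0
        cats = self._split(values, mean, sd)
        if self.recompute_after_outliers and (cats == "outlier").any():
            keep = cats != "outlier"
            if keep.sum() >= 2:
                mean = float(values[keep].mean())
                sd = float(values[keep].std())
                inner = self._split(values[keep], mean, sd)
                # outliers keep their label from the first pass
                inner[inner == "outlier"] = "high"
                cats[keep] = inner
        self.mean_ = mean
        self.sd_ = sd
        self.categories_ = dict(zip(residues, cats.tolist()))
        return self

    def predict(self, X: Mapping[int, float]) -> dict[int, str]:
        """Classify a profile against the fitted thresholds."""
        if not hasattr(self, "mean_"):
            raise AttributeError("PerturbationClassifier must be fitted first")
        residues = sorted(X)
        values = np.array([float(X[r]) for r in residues])
        return dict(zip(residues, self._split(values, self.mean_, self.sd_).tolist()))


def classify_residues(
    profile: Mapping[int, float], recompute_after_outliers: bool = False
) -> ResidueClassification:
    """Classify every residue of a CSP profile; see :class:`PerturbationClassifier`."""
    clf = PerturbationClassifier(recompute_after_outliers=recompute_after_outliers)
    clf.fit(profile)
    return ResidueClassification(
        categories=clf.categories_, mean_csp=clf.mean_, sd_csp=clf.sd_
    )


def _resi_selection(residues: tuple[int, ...]) -> str:
    # PyMOL enumerated selection; indices listed individually, gaps preserved
    return "+".join(str(r) for r in residues)


def render_structure_script(
    classification: ResidueClassification,
    chain_id: str = "A",
    ligand_selection: str | None = None,
    peptide_ligand: bool = False,
) -> str:
    """Emit a PyMOL command script visualizing the classification.

    Highly perturbed residues become red spheres (sphere scale 1.0) on all
    heavy atoms, moderately perturbed residues pink spheres (scale 0.7); the
    backbone is drawn as a gray cartoon and the ligand selection in green
    (sticks for small molecules, cartoon when ``peptide_ligand``).  Outliers
    and background residues are not highlighted.
    """
    if not classification.categories:
        raise ValueError("classification is empty")
    high = classification.residues("high")
    moderate = classification.residues("moderate")
    if not high and not moderate:
        warnings.warn(
            "no residues exceed the perturbation thresholds; the script will "
            "show only the cartoon and ligand",
            stacklevel=2,
        )
    lines = [
        "bg_color white",
        "hide everything",
        f"show cartoon, chain {chain_id}",
        f"color gray80, chain {chain_id}",
    ]
    if high:
        lines += [
            f"select high_csp, chain {chain_id} and resi {_resi_selection(high)} and not hydro",
            "show spheres, high_csp",
            "color red, high_csp",
            "set sphere_scale, 1.0, high_csp",
        ]
    if moderate:
        lines += [
            f"select moderate_csp, chain {chain_id} and resi {_resi_selection(moderate)} and not hydro",
            "show spheres, moderate_csp",
            "color pink, moderate_csp",
            "set sphere_scale, 0.7, moderate_csp",
        ]
    if ligand_selection:
        lines += [
            f"select ligand_sel, {ligand_selection}",
            f"show {'cartoon' if peptide_ligand else 'sticks'}, ligand_sel",
            "color green, ligand_sel",
        ]
    lines.append("deselect")
    return "\n".join(lines) + "\n"
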