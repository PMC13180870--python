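"""Synthetic descriptor fixtures.

Real inputs to this kind of workflow are physicochemical/pharmacokinetic
descriptor tables computed per compound by commercial software, together
with curated activity labels.  Neither is redistributable, so this module
generates statistical stand-ins: class-conditional correlated Gaussian
descriptors from a latent-factor model, with a controllable mean shift
between the active and inactive classes on a chosen subset of descriptors,
plus count-like columns rounded to nonnegative integers (emulating
hydrogen-bond donor/acceptor counts).

The generator is the ground truth for every downstream test: it plants a
known class signal (``class_shift``, in pooled-sd units) that the GAN must
reproduce and the classifier must recover, and it can emit an unlabelled
screening library drawn from the same distributions with the true labels
returned separately.

The fixtures are a statistical stand-in, not a chemical one: no molecular
structures are involved and descriptor names are cosmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tables import ID_COL, LABEL_COL

# Names mimicking common physicochemical descriptor outputs; only the count
# matters downstream.
_NAME_POOL = [
    "mol_MW", "QPlogPo_w", "QPlogS", "donorHB", "accptHB", "PSA",
    "QPPCaco", "QPlogBB", "QPlogKhsa", "QPPMDCK", "volume", "SASA",
    "FOSA", "FISA", "PISA", "WPSA", "dipole", "IP_eV", "EA_eV",
    "glob", "QPpolrz", "QPlogPC16", "QPlogPoct", "QPlogPw", "QPlogHERG",
]

_DEFAULT_INTEGER_COLUMNS = frozenset({3, 4})  # donorHB, accptHB


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the class-conditional latent-factor descriptor model.

    class_shift is the separation between class means on each of the first
    ``n_shifted`` descriptors, in units of that descriptor's pooled sd.
    ``latent_rank`` latent factors induce correlation across descriptors;
    ``noise_sd`` is the residual (idiosyncratic) sd on the latent scale.
    """

    n_active: int = 138
    n_inactive: int = 150
    n_descriptors: int = 50
    class_shift: float = 1.5
    n_shifted: int = 10
    latent_rank: int = 5
    noise_sd: float = 1.0
    integer_columns: frozenset[int] = _DEFAULT_INTEGER_COLUMNS
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_active < 2 or self.n_inactive < 2:
            raise ValidationError("need at least 2 compounds per class")
        if self.n_descriptors < 1:
            raise ValidationError("n_descriptors must be positive")
        if not 0 <= self.n_shifted <= self.n_descriptors:
            raise ValidationError("n_shifted must lie in [0, n_descriptors]")
        if not 1 <= self.latent_rank <= self.n_descriptors:
            raise ValidationError("latent_rank must lie in [1, n_descriptors]")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if any(j < 0 or j >= self.n_descriptors for j in self.integer_columns):
            raise ValidationError("integer_columns out of range")


@dataclass(frozen=True)
class ScreeningLibrarySpec:
    """An unlabelled compound library with a planted active fraction and a
    fraction of compounds whose descriptors are unusable (missing fields)."""

    n_compounds: int = 2648
    true_active_fraction: float = 0.3
    missing_fraction: float = 0.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValidationError("n_compounds must be positive")
        for name in ("true_active_fraction", "missing_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")


def descriptor_names(n: int) -> list[str]:
    names = list(_NAME_POOL[:n])
    names += [f"desc_{i:02d}" for i in range(len(names), n)]
    return names


class _Population:
    """Frozen generating distributions implied by a FixtureSpec.

    The structure (factor loadings, per-descriptor location/scale, class
    mean offsets) depends only on the spec, so a screening library drawn
    later comes from the identical population.
    """

    def __init__(self, spec: FixtureSpec):
        self.spec = spec
        rng = np.random.default_rng([int(spec.seed), 0])
        p, r = spec.n_descriptors, spec.latent_rank
        self.loadings = rng.normal(size=(p, r)) / np.sqrt(r)
        # sd of the latent-scale value: factor part + residual part
        self.latent_sd = np.sqrt((self.loadings**2).sum(axis=1) + spec.noise_sd**2)
        # affine map onto descriptor-like scales
        self.center = rng.uniform(-5.0, 50.0, size=p)
        self.unit = rng.uniform(0.5, 10.0, size=p)
        for j in spec.integer_columns:  # count-like columns: small positive
            self.center[j] = rng.uniform(2.0, 6.0)
            self.unit[j] = rng.uniform(1.0, 2.5)
        self.shift = np.zeros(p)
        self.shift[: spec.n_shifted] = spec.class_shift * self.latent_sd[: spec.n_shifted]

    def sample(self, labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Rows for a vector of 0/1 class codes (1 = active)."""
        spec = self.spec
        n, p = len(labels), spec.n_descriptors
        z = rng.normal(size=(n, spec.latent_rank))
        eps = rng.normal(size=(n, p)) * spec.noise_sd
        latent = z @ self.loadings.T + eps
        latent += np.where(labels[:, None] == 1, 0.5, -0.5) * self.shift[None, :]
        x = self.center[None, :] + self.unit[None, :] * latent
        for j in spec.integer_columns:
            x[:, j] = np.clip(np.round(x[:, j]), 0, None)
        return x


def make_training_fixture(spec: FixtureSpec) -> pd.DataFrame:
    """Labelled descriptor table with exactly the requested class counts.

    Deterministic given ``spec.seed``: repeated calls return bit-identical
    tables.
    """
    pop = _Population(spec)
    rng = np.random.default_rng([int(spec.seed), 1])
    labels = np.concatenate(
        [np.ones(spec.n_active, dtype=int), np.zeros(spec.n_inactive, dtype=int)]
    )
    x = pop.sample(labels, rng)
    n = len(labels)
    table = pd.DataFrame(x, columns=descriptor_names(spec.n_descriptors))
    table.insert(0, ID_COL, [f"CMPD-{i:05d}" for i in range(n)])
    table[LABEL_COL] = np.where(labels == 1, "active", "inactive")
    return table


def make_screening_fixture(
    spec: ScreeningLibrarySpec, training_spec: FixtureSpec
) -> tuple[pd.DataFrame, pd.Series]:
    """Unlabelled library from the training populations, plus hidden truth.

    Each compound is drawn from the active-class distribution with
    probability ``true_active_fraction`` and the inactive one otherwise.
    ``round(n_compounds * missing_fraction)`` compounds get missing (NaN)
    descriptor fields — an empty field once written to CSV — emulating
    library compounds for which descriptor generation fails.
    """
    pop = _Population(training_spec)
    rng = np.random.default_rng([int(spec.seed), 2])
    labels = (rng.random(spec.n_compounds) < spec.true_active_fraction).astype(int)
    x = pop.sample(labels, rng)
    n_missing = int(round(spec.n_compounds * spec.missing_fraction))
    if n_missing:
        rows = rng.choice(spec.n_compounds, size=n_missing, replace=False)
        for i in rows:
            k = rng.integers(1, 4)
            cols = rng.choice(training_spec.n_descriptors, size=k, replace=False)
            x[i, cols] = np.nan
    table = pd.DataFrame(x, columns=descriptor_names(training_spec.n_descriptors))
    ids = [f"LIB-{i:05d}" for i in range(spec.n_compounds)]
    table.insert(0, ID_COL, ids)
    truth = pd.Series(
        np.where(labels == 1, "active", "inactive"), index=pd.Index(ids, name=ID_COL), name=LABEL_COL
    )
    return table, truth
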