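"""Pedigrees and expected kinship.

Family structure is the backbone of the cohort: trait covariance between
relatives enters the association model through a pedigree-derived kinship
matrix used as the covariance of a random effect.  We store kinship
coefficients ``phi`` (probability that two randomly drawn alleles, one from
each individual, are identical by descent); the mixed model uses the
numerator relationship matrix ``A = 2 * phi`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Pedigree", "KinshipMatrix", "build_kinship", "simulate_pedigree"]

MALE = "male"
FEMALE = "female"


@dataclass
class Pedigree:
    """A set of individuals with parent links.

    Parameters
    ----------
    iid : list of str
        Individual identifiers (unique).
    father, mother : list of str or None
        Parent identifiers; ``None`` for founders.  Both parents must be
        given or both absent.
    sex : list of str
        ``"male"`` or ``"female"``.
    family : list of str
        Family identifier per individual.
    """

    iid: list[str]
    father: list[str | None]
    mother: list[str | None]
    sex: list[str]
    family: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.iid)
        if len(set(self.iid)) != n:
            raise ValueError("duplicate individual ids in pedigree")
        if not self.family:
            self.family = ["F1"] * n
        for name in ("father", "mother", "sex", "family"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"pedigree column {name!r} has wrong length")
        idx = self.index
        for i, (f, m) in enumerate(zip(self.father, self.mother)):
            if (f is None) != (m is None):
                raise ValueError(f"individual {self.iid[i]!r} has exactly one parent")
            for p in (f, m):
                if p is not None and p not in idx:
                    raise ValueError(f"unknown parent {p!r} of {self.iid[i]!r}")
            if f is not None and self.sex[idx[f]] == FEMALE:
                raise ValueError(f"father {f!r} of {self.iid[i]!r} is not male")
            if m is not None and self.sex[idx[m]] == MALE:
                raise ValueError(f"mother {m!r} of {self.iid[i]!r} is not female")

    @property
    def n(self) -> int:
        return len(self.iid)

    @property
    def index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.iid)}

    def is_founder(self) -> np.ndarray:
        return np.array([f is None for f in self.father])

    def topological_order(self) -> list[int]:
        """Indices with every parent before its children.

        Raises
        ------
        ValueError
            If the parent links contain a cycle (an individual that is its
            own ancestor); the error names one individual on the cycle.
        """
        idx = self.index
        children: dict[int, list[int]] = {i: [] for i in range(self.n)}
        indeg = np.zeros(self.n, dtype=int)
        for i, (f, m) in enumerate(zip(self.father, self.mother)):
            for p in (f, m):
                if p is not None:
                    children[idx[p]].append(i)
                    indeg[i] += 1
        order = [i for i in range(self.n) if indeg[i] == 0]
        head = 0
        while head < len(order):
            i = order[head]
            head += 1
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    order.append(c)
        if len(order) != self.n:
            bad = self.iid[int(np.flatnonzero(indeg > 0)[0])]
            raise ValueError(f"cycle in pedigree involving individual {bad!r}")
        return order

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "IID": self.iid,
                "FATHER": [f or "0" for f in self.father],
                "MOTHER": [m or "0" for m in self.mother],
                "SEX": self.sex,
                "FAMILY": self.family,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        none = lambda v: None if v in ("0", "", None) or pd.isna(v) else str(v)
        return cls(
            iid=[str(v) for v in df["IID"]],
            father=[none(v) for v in df["FATHER"]],
            mother=[none(v) for v in df["MOTHER"]],
            sex=list(df["SEX"]),
            family=list(df["FAMILY"]) if "FAMILY" in df else [],
        )


@dataclass
class KinshipMatrix:
    """Expected kinship coefficients phi (not 2*phi) with sample ids."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("kinship matrix shape inconsistent with ids")
        if not np.allclose(v, v.T):
            raise ValueError("kinship matrix not symmetric")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def relationship(self) -> np.ndarray:
        """Numerator relationship matrix A = 2 * phi."""
        return 2.0 * self.values

    @classmethod
    def identity(cls, ids: list[str]) -> "KinshipMatrix":
        """Unrelated, non-inbred individuals: phi = I/2, i.e. A = I."""
        return cls(0.5 * np.eye(len(ids)), list(ids))


def build_kinship(pedigree: Pedigree) -> KinshipMatrix:
    """Expected kinship from a pedigree by the recursive tabular method.

    Founders are assumed unrelated and non-inbred (phi_ii = 1/2).  For a
    non-founder ``i`` with parents ``f`` and ``m``::

        phi(i, j) = (phi(f, j) + phi(m, j)) / 2      for j already placed
        phi(i, i) = (1 + phi(f, m)) / 2

    Deterministic; rows are filled in generation (topological) order.
    """
    order = pedigree.topological_order()
    idx = pedigree.index
    n = pedigree.n
    phi = np.zeros((n, n))
    placed = np.zeros(n, dtype=bool)
    for i in order:
        f, m = pedigree.father[i], pedigree.mother[i]
        if f is None:
            phi[i, i] = 0.5
        else:
            fi, mi = idx[f], idx[m]
            prev = placed.copy()
            row = 0.5 * (phi[fi] + phi[mi])
            phi[i, prev] = row[prev]
            phi[prev, i] = row[prev]
            phi[i, i] = 0.5 * (1.0 + phi[fi, mi])
        placed[i] = True
    return KinshipMatrix(phi, list(pedigree.iid))


def simulate_pedigree(
    n_families: int,
    *,
    children_per_couple: tuple[int, int] = (2, 4),
    n_generations: int = 3,
    seed: int | np.random.Generator = 0,
) -> Pedigree:
    """Generate three-generation families of the proband/offspring kind.

    Each family starts from a founder couple; each of their children marries
    an unrelated spouse and has children of their own, for ``n_generations``
    generations in total.  Family sizes are drawn uniformly from
    ``children_per_couple`` (inclusive).
    """
    if n_families <= 0:
        raise ValueError("n_families must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    iid: list[str] = []
    father: list[str | None] = []
    mother: list[str | None] = []
    sex: list[str] = []
    family: list[str] = []

    def add(fam: str, tag: str, sx: str, f: str | None = None, m: str | None = None) -> str:
        name = f"{fam}_{tag}"
        iid.append(name)
        father.append(f)
        mother.append(m)
        sex.append(sx)
        family.append(fam)
        return name

    lo, hi = children_per_couple
    for k in range(n_families):
        fam = f"FAM{k + 1:03d}"
        serial = 0
        couples = [(add(fam, "P1", MALE), add(fam, "P2", FEMALE))]
        for _gen in range(1, n_generations):
            next_couples = []
            for dad, mom in couples:
                for _c in range(rng.integers(lo, hi + 1)):
                    serial += 1
                    sx = MALE if rng.random() < 0.5 else FEMALE
                    child = add(fam, f"I{serial}", sx, dad, mom)
                    serial += 1
                    spouse_sex = FEMALE if sx == MALE else MALE
                    spouse = add(fam, f"S{serial}", spouse_sex)
                    next_couples.append((child, spouse) if sx == MALE else (spouse, child))
            couples = next_couples
    return Pedigree(iid, father, mother, sex, family)
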