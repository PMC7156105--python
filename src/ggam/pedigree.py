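"""Pedigree machinery for genetic-groups animal models.

A pedigree is a directed acyclic parent map with, per individual, an
identifier, dam, sire (either possibly unknown), sex, cohort year, and an
immigrant flag.  From it this module computes:

* genetic-group coefficients ``q_i`` — the expected fraction of individual
  *i*'s genome descending from the immigrant group, obtained by assigning
  every unknown-parent ("phantom") slot to either the *founder* or the
  *immigrant* group and halving-and-summing down the pedigree;
* the inverse additive (numerator) relationship matrix ``A^-1`` by the
  Henderson rules with inbreeding-aware Mendelian-sampling variances;
* pairwise kinship coefficients and inbreeding coefficients by the tabular
  recursion.

Unknown parents are represented as ``None`` internally; readers normalise
the common file conventions (empty string, ``NA``, ``0``) to unknown.
"""

from __future__ import annotations

import dataclasses
from collections import deque
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "PedigreeError",
    "Pedigree",
    "GroupCoefficients",
    "RelatednessInverse",
    "read_pedigree",
    "write_pedigree",
    "prune_pedigree",
    "assign_genetic_groups",
    "compute_q",
    "compute_A_inverse",
    "compute_kinship",
    "inbreeding_coefficients",
    "write_A_inverse",
]

DEFAULT_MISSING_TOKENS = ("", "NA", "NaN", "nan", "0", "*", ".")

FOUNDER_GROUP = "founder"
IMMIGRANT_GROUP = "immigrant"


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, sex conflicts, ...)."""


@dataclasses.dataclass(frozen=True)
class Pedigree:
    """A validated pedigree.

    Attributes
    ----------
    df : pandas.DataFrame
        Columns ``id, dam, sire, sex, cohort, immigrant``; ``dam``/``sire``
        are ``None`` when unknown, ``sex`` is ``"F"``/``"M"``/``None``,
        ``cohort`` an integer year or ``None``, ``immigrant`` boolean.
        Rows are stored in a topological order (parents before offspring).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        _validate(self.df)
        order = _topological_order(self.df)
        object.__setattr__(self, "df", self.df.loc[order].reset_index(drop=True))

    # -- conveniences -------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return list(self.df["id"])

    @property
    def n(self) -> int:
        return len(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, identifier: str) -> bool:
        return str(identifier) in set(self.df["id"])

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Dam/sire positions in topological order; -1 where unknown."""
        pos = {i: k for k, i in enumerate(self.df["id"])}
        dam = np.array([pos.get(d, -1) if d is not None else -1 for d in self.df["dam"]])
        sire = np.array([pos.get(s, -1) if s is not None else -1 for s in self.df["sire"]])
        return dam, sire


@dataclasses.dataclass(frozen=True)
class GroupCoefficients:
    """Per-individual immigrant genetic-group coefficients.

    ``q`` maps identifier -> expected genome fraction from the immigrant
    group (in [0, 1]); ``var_q`` is the sample variance of q across the
    designated phenotyped individuals.
    """

    q: pd.Series
    var_q: float

    def __post_init__(self) -> None:
        vals = self.q.to_numpy(dtype=float)
        if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
            raise ValueError("group coefficients must lie in [0, 1]")
        if self.var_q < 0:
            raise ValueError("var_q must be nonnegative")

    def __getitem__(self, identifier: str) -> float:
        return float(self.q[str(identifier)])


@dataclasses.dataclass(frozen=True)
class RelatednessInverse:
    """Sparse inverse additive relationship matrix with inbreeding."""

    order: list[str]
    entries: sp.csr_matrix
    inbreeding: pd.Series

    def __post_init__(self) -> None:
        asym = abs(self.entries - self.entries.T)
        if asym.nnz and asym.max() > 1e-10:
            raise ValueError("A-inverse must be symmetric")


# ----------------------------------------------------------------------
# construction / validation
# ----------------------------------------------------------------------

def _norm_id(value, missing_tokens) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip()
    if text in missing_tokens:
        return None
    return text


def _validate(df: pd.DataFrame) -> None:
    ids = list(df["id"])
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise PedigreeError(f"duplicate individual ids: {dupes[:5]}")
    known = set(ids)
    dam_of = dict(zip(df["id"], df["dam"]))
    sire_of = dict(zip(df["id"], df["sire"]))
    for col, role, sex in (("dam", "dam", "F"), ("sire", "sire", "M")):
        for child, parent in zip(df["id"], df[col]):
            if parent is None:
                continue
            if parent == child:
                raise PedigreeError(f"cycle: individual {child!r} is its own {role}")
            if parent not in known:
                raise PedigreeError(f"{role} {parent!r} of {child!r} is not a pedigree record")
    # sex consistency: appearing as dam forces F, as sire forces M
    implied: dict[str, str] = {}
    for child in df["id"]:
        d, s = dam_of[child], sire_of[child]
        if d is not None:
            if implied.get(d, "F") != "F":
                raise PedigreeError(f"sex conflict: {d!r} appears as both dam and sire")
            implied[d] = "F"
        if s is not None:
            if implied.get(s, "M") != "M":
                raise PedigreeError(f"sex conflict: {s!r} appears as both dam and sire")
            implied[s] = "M"
    for ident, sex in zip(df["id"], df["sex"]):
        if sex is not None and ident in implied and implied[ident] != sex:
            role = "dam" if implied[ident] == "F" else "sire"
            raise PedigreeError(
                f"sex conflict: {ident!r} recorded as sex {sex} but appears as {role}"
            )
    for ident, d, s, imm in zip(df["id"], df["dam"], df["sire"], df["immigrant"]):
        if imm and (d is not None or s is not None):
            raise PedigreeError(
                f"immigrant {ident!r} has a named parent; immigrants must be parentless"
            )


def _topological_order(df: pd.DataFrame) -> list[int]:
    """Kahn's algorithm over the parent->child DAG; raises on cycles."""
    idx_of = {i: k for k, i in enumerate(df["id"])}
    n = len(df)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=int)
    for k, (d, s) in enumerate(zip(df["dam"], df["sire"])):
        for p in (d, s):
            if p is not None:
                children[idx_of[p]].append(k)
                indeg[k] += 1
    queue = deque(int(k) for k in np.flatnonzero(indeg == 0))
    order: list[int] = []
    while queue:
        k = queue.popleft()
        order.append(k)
        for c in children[k]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) < n:
        stuck = [df["id"].iloc[k] for k in range(n) if indeg[k] > 0]
        raise PedigreeError(f"pedigree contains a cycle among: {stuck[:10]}")
    return order


def pedigree_from_frame(
    df: pd.DataFrame,
    dialect: Mapping[str, str] | None = None,
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
) -> Pedigree:
    """Build a validated :class:`Pedigree` from a raw table.

    ``dialect`` maps canonical column names (``id``, ``dam``, ``sire``,
    ``sex``, ``cohort``, ``immigrant``) to the file's column names; only the
    first three are required.
    """
    dialect = dict(dialect or {})
    cols = {c: dialect.get(c, c) for c in ("id", "dam", "sire", "sex", "cohort", "immigrant")}
    for required in ("id", "dam", "sire"):
        if cols[required] not in df.columns:
            raise PedigreeError(f"missing required pedigree column {cols[required]!r}")
    tokens = set(missing_tokens)
    out = pd.DataFrame(
        {
            "id": [_norm_id(v, ()) for v in df[cols["id"]]],
            "dam": [_norm_id(v, tokens) for v in df[cols["dam"]]],
            "sire": [_norm_id(v, tokens) for v in df[cols["sire"]]],
        }
    )
    if cols["sex"] in df.columns:
        out["sex"] = [
            None if _norm_id(v, tokens) is None else str(v).strip().upper()[0]
            for v in df[cols["sex"]]
        ]
    else:
        out["sex"] = None
    if cols["cohort"] in df.columns:
        out["cohort"] = [
            None if _norm_id(v, {"", "NA", "NaN", "nan"}) is None else int(float(v))
            for v in df[cols["cohort"]]
        ]
    else:
        out["cohort"] = None
    if cols["immigrant"] in df.columns:
        out["immigrant"] = [
            str(v).strip().lower() in ("1", "true", "t", "yes", "y")
            for v in df[cols["immigrant"]]
        ]
    else:
        out["immigrant"] = False
    return Pedigree(out)


def read_pedigree(
    path,
    dialect: Mapping[str, str] | None = None,
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
) -> Pedigree:
    """Read and validate a pedigree CSV."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    return pedigree_from_frame(raw, dialect=dialect, missing_tokens=missing_tokens)


def write_pedigree(ped: Pedigree, path) -> None:
    df = ped.df.copy()
    df["dam"] = df["dam"].map(lambda v: "" if v is None else v)
    df["sire"] = df["sire"].map(lambda v: "" if v is None else v)
    df["sex"] = df["sex"].map(lambda v: "" if v is None else v)
    df["cohort"] = df["cohort"].map(lambda v: "" if v is None else v)
    df["immigrant"] = df["immigrant"].astype(int)
    df.to_csv(path, index=False)


# ----------------------------------------------------------------------
# pruning
# ----------------------------------------------------------------------

def prune_pedigree(ped: Pedigree, phenotyped: Iterable[str]) -> Pedigree:
    """Retain exactly the phenotyped individuals and all their ancestors."""
    phenotyped = {str(p) for p in phenotyped}
    known = set(ped.df["id"])
    missing = sorted(phenotyped - known)
    if missing:
        raise PedigreeError(f"phenotyped ids absent from pedigree: {missing[:10]}")
    dam_of = dict(zip(ped.df["id"], ped.df["dam"]))
    sire_of = dict(zip(ped.df["id"], ped.df["sire"]))
    keep: set[str] = set()
    stack = list(phenotyped)
    while stack:
        i = stack.pop()
        if i in keep:
            continue
        keep.add(i)
        for p in (dam_of[i], sire_of[i]):
            if p is not None and p not in keep:
                stack.append(p)
    sub = ped.df[ped.df["id"].isin(keep)].reset_index(drop=True)
    return Pedigree(sub)


# ----------------------------------------------------------------------
# genetic groups and q coefficients
# ----------------------------------------------------------------------

def assign_genetic_groups(ped: Pedigree, cutoff_year: int | None = None) -> dict[tuple[str, str], str]:
    """Assign every phantom (unknown-parent) slot to a genetic group.

    Phantom parents of flagged immigrants (with cohort >= ``cutoff_year``
    when a cutoff is given and the cohort is known) join the immigrant
    group; all other phantom slots join the founder group.
    """
    groups: dict[tuple[str, str], str] = {}
    for ident, dam, sire, cohort, imm in zip(
        ped.df["id"], ped.df["dam"], ped.df["sire"], ped.df["cohort"], ped.df["immigrant"]
    ):
        recent = bool(imm)
        if recent and cutoff_year is not None and cohort is not None:
            recent = cohort >= cutoff_year
        group = IMMIGRANT_GROUP if recent else FOUNDER_GROUP
        if dam is None:
            groups[(ident, "dam")] = group
        if sire is None:
            groups[(ident, "sire")] = group
    return groups


def compute_q(
    ped: Pedigree,
    groups: Mapping[tuple[str, str], str],
    phenotyped: Iterable[str] | None = None,
) -> GroupCoefficients:
    """Immigrant-group coefficients by the halving recursion.

    ``q_child = (q_dam + q_sire) / 2`` with each phantom slot contributing 1
    (immigrant group) or 0 (founder group).  ``var_q`` is the sample
    variance of q over the phenotyped set (all individuals if omitted).
    """
    dam_pos, sire_pos = ped.parent_indices()
    ids = ped.ids
    q = np.zeros(ped.n)
    for k, ident in enumerate(ids):
        contrib = 0.0
        for slot, pos in (("dam", dam_pos[k]), ("sire", sire_pos[k])):
            if pos >= 0:
                contrib += q[pos]
            else:
                key = (ident, slot)
                if key not in groups:
                    raise PedigreeError(f"phantom slot {key} has no genetic-group assignment")
                contrib += 1.0 if groups[key] == IMMIGRANT_GROUP else 0.0
        q[k] = contrib / 2.0
    series = pd.Series(q, index=ids, name="q")
    focal = series if phenotyped is None else series[[str(p) for p in phenotyped]]
    var_q = float(focal.var(ddof=1)) if len(focal) > 1 else 0.0
    return GroupCoefficients(q=series, var_q=var_q)


# ----------------------------------------------------------------------
# kinship, inbreeding, A-inverse
# ----------------------------------------------------------------------

def _kinship_matrix(ped: Pedigree) -> np.ndarray:
    """Dense kinship matrix by the bottom-up tabular recursion.

    phi(i, j) = 0.5 * (phi(dam_i, j) + phi(sire_i, j)) for j preceding i in
    topological order, phi(i, i) = 0.5 * (1 + F_i) with F_i = phi(dam_i,
    sire_i); unknown parents contribute zero kinship.
    """
    dam, sire = ped.parent_indices()
    n = ped.n
    phi = np.zeros((n, n))
    for i in range(n):
        d, s = dam[i], sire[i]
        row = np.zeros(i)
        if d >= 0:
            row += 0.5 * phi[d, :i]
        if s >= 0:
            row += 0.5 * phi[s, :i]
        phi[i, :i] = row
        phi[:i, i] = row
        f_i = phi[d, s] if (d >= 0 and s >= 0) else 0.0
        phi[i, i] = 0.5 * (1.0 + f_i)
    return phi


def inbreeding_coefficients(ped: Pedigree) -> pd.Series:
    """Per-individual inbreeding coefficient F (kinship of the parents)."""
    phi = _kinship_matrix(ped)
    return pd.Series(2.0 * np.diag(phi) - 1.0, index=ped.ids, name="F")


def compute_kinship(
    ped: Pedigree,
    pairs: Sequence[tuple[str, str]] | None = None,
):
    """Pairwise kinship coefficients.

    Returns the full symmetric matrix as a DataFrame when ``pairs`` is
    omitted, else a dict mapping each requested pair to its coefficient.
    """
    phi = _kinship_matrix(ped)
    if pairs is None:
        return pd.DataFrame(phi, index=ped.ids, columns=ped.ids)
    pos = {i: k for k, i in enumerate(ped.ids)}
    return {(a, b): float(phi[pos[str(a)], pos[str(b)]]) for a, b in pairs}


def mean_pairwise_kinship(ped: Pedigree, individuals: Iterable[str]) -> tuple[float, float]:
    """Mean and SD of kinship over all unordered distinct pairs of a set."""
    idx = [ped.ids.index(str(i)) for i in individuals]
    phi = _kinship_matrix(ped)
    sub = phi[np.ix_(idx, idx)]
    tri = sub[np.triu_indices(len(idx), k=1)]
    if tri.size == 0:
        return float("nan"), float("nan")
    return float(tri.mean()), float(tri.std(ddof=1))


def compute_A_inverse(ped: Pedigree) -> RelatednessInverse:
    """Sparse A^-1 by the Henderson rules with inbreeding.

    Mendelian-sampling variances d_i use the parents' inbreeding
    coefficients: d_i = 0.5 - 0.25 (F_dam + F_sire) with an unknown parent
    contributing F = -1 (so a fully unknown individual gets d_i = 1).
    """
    F = inbreeding_coefficients(ped)
    dam, sire = ped.parent_indices()
    f_arr = F.to_numpy()
    n = ped.n
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i: int, j: int, v: float) -> None:
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        d, s = dam[i], sire[i]
        f_d = f_arr[d] if d >= 0 else -1.0
        f_s = f_arr[s] if s >= 0 else -1.0
        d_i = 0.5 - 0.25 * (f_d + f_s)
        alpha = 1.0 / d_i
        add(i, i, alpha)
        for p in (d, s):
            if p >= 0:
                add(i, p, -alpha / 2.0)
                add(p, i, -alpha / 2.0)
        for p in (d, s):
            for r in (d, s):
                if p >= 0 and r >= 0:
                    add(p, r, alpha / 4.0)
    ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    ainv.sum_duplicates()
    return RelatednessInverse(order=ped.ids, entries=ainv, inbreeding=F)


def write_A_inverse(rel: RelatednessInverse, path) -> None:
    """Write A^-1 as (row-id, col-id, value) triplets, lower triangle."""
    coo = sp.tril(rel.entries).tocoo()
    with open(path, "w") as fh:
        fh.write("row\tcol\tvalue\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{rel.order[i]}\t{rel.order[j]}\t{v:.12g}\n")
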