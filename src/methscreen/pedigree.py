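"""Pedigree parsing, kinship computation and sibling-pair enumeration.

A pedigree is the backbone of the whole analysis: it supplies the ordered
sibling pairs used to estimate familiality (scor) and the expected kinship
matrix whose doubled value (the additive relatedness matrix) is the random
effect covariance in the meQTL mixed model.

Kinship coefficients phi(i, j) — the probability that one allele drawn at
random from i and one from j are identical by descent — are computed with
the standard recursive tabular method, processing individuals so that
parents precede children:

    phi(i, i) = 1/2 + 1/2 * phi(father_i, mother_i)
    phi(i, j) = 1/2 * (phi(father_i, j) + phi(mother_i, j))   (j earlier)

Founders are taken as non-inbred and mutually unrelated; individuals in
different pedigrees have phi = 0 (the matrix is block diagonal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "KinshipMatrix",
    "SiblingPair",
    "PedigreeError",
    "read_pedigree",
    "compute_kinship",
    "monte_carlo_kinship",
    "extract_sibling_pairs",
    "restrict_pairs",
    "write_kinship",
    "read_kinship",
]

MISSING = "0"  # conventional missing-parent code

SEX_CODES = {"1": "male", "2": "female"}


class PedigreeError(ValueError):
    """Structural or format problem in a pedigree file."""


@dataclass(frozen=True)
class SiblingPair:
    """A full-sibling pair ordered so `first` is the earlier-born member."""

    first: str
    second: str
    pedigree_id: str


@dataclass
class Pedigree:
    """Validated pedigree records.

    ``table`` has one row per individual with columns ``pedigree_id``,
    ``individual_id``, ``father_id``, ``mother_id`` (None when missing),
    ``sex`` ({'male','female','unknown'}) and ``birth_order`` (nullable int).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self._validate()

    # -- basic accessors -------------------------------------------------
    @property
    def individual_ids(self) -> list[str]:
        return list(self.table["individual_id"])

    @property
    def n_individuals(self) -> int:
        return len(self.table)

    @property
    def pedigree_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["pedigree_id"]))

    def founders(self) -> list[str]:
        t = self.table
        mask = t["father_id"].isna() & t["mother_id"].isna()
        return list(t.loc[mask, "individual_id"])

    def _validate(self) -> None:
        t = self.table
        dup = t["individual_id"][t["individual_id"].duplicated()]
        if len(dup):
            raise PedigreeError(f"duplicated individual_id: {dup.iloc[0]!r}")
        ids = dict(zip(t["individual_id"], t["pedigree_id"]))
        for _, row in t.iterrows():
            fa, mo = row["father_id"], row["mother_id"]
            if (fa is None or pd.isna(fa)) != (mo is None or pd.isna(mo)):
                raise PedigreeError(
                    f"individual {row['individual_id']!r} has exactly one known "
                    "parent; founders must have both parents missing"
                )
            for par in (fa, mo):
                if par is None or pd.isna(par):
                    continue
                if par not in ids:
                    raise PedigreeError(
                        f"parent {par!r} of {row['individual_id']!r} is not in the file"
                    )
                if ids[par] != row["pedigree_id"]:
                    raise PedigreeError(
                        f"parent {par!r} of {row['individual_id']!r} belongs to a "
                        "different pedigree"
                    )
        self.topological_order()  # raises on cycles

    def topological_order(self) -> list[str]:
        """Individual ids ordered so every parent precedes its children.

        Raises :class:`PedigreeError` if the parentage graph has a cycle
        (e.g. an individual listed as its own ancestor).
        """
        t = self.table
        parents = {
            r["individual_id"]: [p for p in (r["father_id"], r["mother_id"]) if p is not None and not pd.isna(p)]
            for _, r in t.iterrows()
        }
        indeg = {iid: len(ps) for iid, ps in parents.items()}
        children: dict[str, list[str]] = {iid: [] for iid in parents}
        for iid, ps in parents.items():
            for p in ps:
                children[p].append(iid)
        queue = [iid for iid in t["individual_id"] if indeg[iid] == 0]
        order: list[str] = []
        while queue:
            iid = queue.pop()
            order.append(iid)
            for ch in children[iid]:
                indeg[ch] -= 1
                if indeg[ch] == 0:
                    queue.append(ch)
        if len(order) != len(parents):
            stuck = sorted(iid for iid, d in indeg.items() if d > 0)
            raise PedigreeError(f"pedigree contains a parentage cycle involving {stuck[0]!r}")
        return order


@dataclass
class KinshipMatrix:
    """Symmetric kinship coefficients phi over an ordered sample list."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("kinship matrix shape does not match sample_ids")

    def relatedness(self) -> np.ndarray:
        """The additive relatedness matrix 2*phi used as LMM covariance."""
        return 2.0 * self.values

    def subset(self, sample_ids: list[str]) -> "KinshipMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in sample_ids])
        return KinshipMatrix(list(sample_ids), self.values[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# I/O


def read_pedigree(path: str, dialect: str = "fam") -> Pedigree:
    """Read a whitespace-delimited 6-column pedigree file.

    Dialects:

    ``fam``
        PLINK .fam: family, individual, father, mother, sex, phenotype.
        The phenotype column is ignored; birth order is missing.
    ``fam_birthorder``
        As ``fam`` but the sixth column is interpreted as birth order
        (0 or negative = missing).
    ``ped``
        Six leading columns as ``fam``; any further columns are ignored.
    """
    if dialect not in {"fam", "fam_birthorder", "ped"}:
        raise ValueError(f"unknown pedigree dialect {dialect!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) < 6:
                raise PedigreeError(f"{path}:{lineno}: expected >= 6 columns, got {len(parts)}")
            fid, iid, fa, mo, sex, sixth = parts[:6]
            birth_order = None
            if dialect == "fam_birthorder":
                try:
                    bo = int(float(sixth))
                except ValueError as exc:
                    raise PedigreeError(f"{path}:{lineno}: bad birth order {sixth!r}") from exc
                birth_order = bo if bo > 0 else None
            rows.append(
                {
                    "pedigree_id": fid,
                    "individual_id": iid,
                    "father_id": None if fa == MISSING else fa,
                    "mother_id": None if mo == MISSING else mo,
                    "sex": SEX_CODES.get(sex, "unknown"),
                    "birth_order": birth_order,
                }
            )
    if not rows:
        raise PedigreeError(f"{path}: no pedigree records")
    table = pd.DataFrame(rows)
    table["birth_order"] = table["birth_order"].astype("Int64")
    return Pedigree(table)


def write_pedigree(ped: Pedigree, path: str, dialect: str = "fam_birthorder") -> None:
    """Write a pedigree in PLINK-style 6-column format."""
    inv_sex = {"male": "1", "female": "2", "unknown": "0"}
    with open(path, "w") as fh:
        for _, r in ped.table.iterrows():
            bo = r["birth_order"]
            sixth = str(int(bo)) if dialect == "fam_birthorder" and pd.notna(bo) else "0"
            fh.write(
                "\t".join(
                    [
                        r["pedigree_id"],
                        r["individual_id"],
                        r["father_id"] or MISSING,
                        r["mother_id"] or MISSING,
                        inv_sex[r["sex"]],
                        sixth,
                    ]
                )
                + "\n"
            )


def write_kinship(kin: KinshipMatrix, path: str) -> None:
    df = pd.DataFrame(kin.values, index=kin.sample_ids, columns=kin.sample_ids)
    df.to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")


def read_kinship(path: str) -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return KinshipMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Kinship


def compute_kinship(ped: Pedigree) -> KinshipMatrix:
    """Expected kinship by the recursive tabular method, block per pedigree."""
    order = ped.topological_order()
    t = ped.table.set_index("individual_id")
    all_ids = ped.individual_ids
    pos = {iid: i for i, iid in enumerate(all_ids)}
    n = len(all_ids)
    phi = np.zeros((n, n))

    # per-pedigree blocks keep the O(n^2) recursion local
    for pid in ped.pedigree_ids:
        members = [iid for iid in order if t.at[iid, "pedigree_id"] == pid]
        k = len(members)
        local = {iid: i for i, iid in enumerate(members)}
        block = np.zeros((k, k))
        for iid in members:
            i = local[iid]
            fa, mo = t.at[iid, "father_id"], t.at[iid, "mother_id"]
            if fa is None or pd.isna(fa):
                block[i, i] = 0.5
                continue  # founder: unrelated to everyone earlier
            fi, mi = local[fa], local[mo]
            for jid in members[:i]:
                j = local[jid]
                val = 0.5 * (block[fi, j] + block[mi, j])
                block[i, j] = block[j, i] = val
            block[i, i] = 0.5 + 0.5 * block[fi, mi]
        gidx = np.array([pos[iid] for iid in members])
        phi[np.ix_(gidx, gidx)] = block
    return KinshipMatrix(all_ids, phi)


def monte_carlo_kinship(
    ped: Pedigree, n_replicates: int = 100_000, rng: np.random.Generator | None = None
) -> KinshipMatrix:
    """Estimate kinship by gene-dropping unique founder alleles.

    Each replicate assigns every founder two globally unique allele labels
    and transmits one uniformly chosen parental allele per meiosis down the
    pedigree.  phi(i, j) is then estimated as the probability that an allele
    drawn at random from i matches one drawn at random from j, averaged over
    the four ordered allele pairs.  This is an independent, stochastic route
    to the same quantity as :func:`compute_kinship` and is intended for
    validation, not production use.
    """
    if rng is None:
        rng = np.random.default_rng()
    order = ped.topological_order()
    t = ped.table.set_index("individual_id")
    pos = {iid: i for i, iid in enumerate(ped.individual_ids)}
    n = len(pos)

    a1 = np.empty((n_replicates, n), dtype=np.int32)
    a2 = np.empty((n_replicates, n), dtype=np.int32)
    label = 0
    for iid in order:
        i = pos[iid]
        fa, mo = t.at[iid, "father_id"], t.at[iid, "mother_id"]
        if fa is None or pd.isna(fa):
            a1[:, i] = 2 * label
            a2[:, i] = 2 * label + 1
            label += 1
        else:
            fi, mi = pos[fa], pos[mo]
            pick_f = rng.integers(0, 2, size=n_replicates, dtype=np.int8)
            pick_m = rng.integers(0, 2, size=n_replicates, dtype=np.int8)
            a1[:, i] = np.where(pick_f == 0, a1[:, fi], a2[:, fi])
            a2[:, i] = np.where(pick_m == 0, a1[:, mi], a2[:, mi])

    phi = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            match = (
                (a1[:, i] == a1[:, j]).mean()
                + (a1[:, i] == a2[:, j]).mean()
                + (a2[:, i] == a1[:, j]).mean()
                + (a2[:, i] == a2[:, j]).mean()
            ) / 4.0
            phi[i, j] = phi[j, i] = match
    return KinshipMatrix(ped.individual_ids, phi)


# ---------------------------------------------------------------------------
# Sibling pairs


def _sib_sort_key(row: pd.Series) -> tuple:
    bo = row["birth_order"]
    return (float("inf") if pd.isna(bo) else int(bo), row["individual_id"])


def extract_sibling_pairs(ped: Pedigree, one_pair_per_sibship: bool = False) -> list[SiblingPair]:
    """All distinct full-sibling pairs, each ordered earlier-born first.

    Siblings share both a father and a mother.  Within a sibship of size k
    every one of the k*(k-1)/2 pairs is emitted, ordered by birth order
    (ties or missing birth orders broken by individual_id, lexicographic);
    with ``one_pair_per_sibship`` only the two earliest-born contribute.
    """
    t = ped.table
    sibs = t[t["father_id"].notna() & t["mother_id"].notna()]
    pairs: list[SiblingPair] = []
    for (pid, _fa, _mo), grp in sibs.groupby(
        ["pedigree_id", "father_id", "mother_id"], sort=True
    ):
        members = sorted((row for _, row in grp.iterrows()), key=_sib_sort_key)
        if one_pair_per_sibship:
            members = members[:2]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pairs.append(
                    SiblingPair(
                        members[i]["individual_id"], members[j]["individual_id"], pid
                    )
                )
    return pairs


def restrict_pairs(pairs: list[SiblingPair], available: set[str]) -> list[SiblingPair]:
    """Pairs whose both members are in `available` (e.g. one treatment phase)."""
    return [p for p in pairs if p.first in available and p.second in available]
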