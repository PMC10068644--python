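"""Pedigree construction, validation and the additive relationship matrix.

Pedigrees are held as a pandas DataFrame with one row per individual and
columns ``family_id, individual_id, father_id, mother_id, sex`` (missing
parents are empty strings; sex is "male"/"female").  Founders have both
parents missing.  The additive (numerator) relationship matrix A is built by
the recursive tabular method over generation-sorted individuals:

    A[i,i] = 1 + 0.5 * A[father_i, mother_i]
    A[i,j] = 0.5 * (A[j, father_i] + A[j, mother_i])   for j before i

so full sibs share 0.5 and grandparent-grandchild pairs 0.25 in the absence
of inbreeding.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PED_COLUMNS = ["family_id", "individual_id", "father_id", "mother_id", "sex"]
MISSING_PARENT = ""

_SEX_TO_PED = {"male": "1", "female": "2"}
_PED_TO_SEX = {"1": "male", "2": "female"}


class PedigreeError(ValueError):
    pass


def validate_pedigree(ped: pd.DataFrame) -> None:
    """Check uniqueness, parent presence, sex consistency and acyclicity."""
    missing_cols = set(PED_COLUMNS) - set(ped.columns)
    if missing_cols:
        raise PedigreeError(f"pedigree missing columns: {sorted(missing_cols)}")
    ids = ped["individual_id"]
    if ids.duplicated().any():
        raise PedigreeError("individual_ids are not unique")
    fam_of = dict(zip(ped["individual_id"], ped["family_id"]))
    sex_of = dict(zip(ped["individual_id"], ped["sex"]))
    for _, row in ped.iterrows():
        for col, want_sex in (("father_id", "male"), ("mother_id", "female")):
            parent = row[col]
            if parent == MISSING_PARENT:
                continue
            if parent not in fam_of:
                raise PedigreeError(f"{col} {parent!r} of {row['individual_id']!r} not in pedigree")
            if fam_of[parent] != row["family_id"]:
                raise PedigreeError(f"parent {parent!r} is in a different family")
            if sex_of[parent] != want_sex:
                raise PedigreeError(f"{col} {parent!r} has sex {sex_of[parent]!r}")
    generation_order(ped)  # raises on cycles


def generation_order(ped: pd.DataFrame) -> list[str]:
    """Topological order: every parent precedes all of its children.

    Raises PedigreeError if the parent links contain a cycle (an individual
    that is its own ancestor).
    """
    parents = {
        row.individual_id: [p for p in (row.father_id, row.mother_id) if p != MISSING_PARENT]
        for row in ped.itertuples()
    }
    order: list[str] = []
    state: dict[str, int] = {}  # 0=visiting, 1=done

    for root in parents:
        if root in state:
            continue
        stack = [(root, iter(parents[root]))]
        state[root] = 0
        while stack:
            node, it = stack[-1]
            advanced = False
            for p in it:
                if p not in parents:
                    continue
                s = state.get(p)
                if s == 0:
                    raise PedigreeError(f"pedigree cycle involving {p!r}")
                if s is None:
                    state[p] = 0
                    stack.append((p, iter(parents[p])))
                    advanced = True
                    break
            if not advanced:
                stack.pop()
                state[node] = 1
                order.append(node)
    return order


def build_relationship_matrix(ped: pd.DataFrame) -> pd.DataFrame:
    """Additive relationship matrix A via the recursive tabular method."""
    validate_pedigree(ped)
    order = generation_order(ped)
    idx = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    parent_of = {
        row.individual_id: (row.father_id, row.mother_id)
        for row in ped.itertuples()
    }
    A = np.zeros((n, n))
    for i, iid in enumerate(order):
        f, m = parent_of[iid]
        fi = idx.get(f, -1) if f != MISSING_PARENT else -1
        mi = idx.get(m, -1) if m != MISSING_PARENT else -1
        a_fm = A[fi, mi] if fi >= 0 and mi >= 0 else 0.0
        A[i, i] = 1.0 + 0.5 * a_fm
        for j in range(i):
            val = 0.0
            if fi >= 0:
                val += 0.5 * A[j, fi]
            if mi >= 0:
                val += 0.5 * A[j, mi]
            A[i, j] = A[j, i] = val
    out = pd.DataFrame(A, index=order, columns=order)
    # present in the input's row order, not generation order
    ids = list(ped["individual_id"])
    return out.loc[ids, ids]


def generate_pedigree(
    n_families: int,
    family_size_range: tuple[int, int],
    seed: int,
    fraction_female: float = 0.5,
    total_size: int | None = None,
) -> pd.DataFrame:
    """Generate a multi-family pedigree with non-trivial relatedness.

    Each family of target size s has, for s > 4, two founder couples whose
    children form the second generation; one child from each couple is mated
    to produce third-generation grandchildren, giving relationship entries of
    0.5 (parent-offspring, full sibs) and 0.25 (grandparental, avuncular).
    Families of size <= 4 are founders only.  When ``total_size`` is given,
    the drawn family sizes are nudged within the range until they sum to it.
    """
    lo, hi = family_size_range
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if lo < 1 or lo > hi:
        raise ValueError(f"invalid family_size_range {family_size_range}")
    if not 0.0 <= fraction_female <= 1.0:
        raise ValueError("fraction_female must be in [0, 1]")
    if total_size is not None and not (n_families * lo <= total_size <= n_families * hi):
        raise ValueError(f"total_size {total_size} unreachable with "
                         f"{n_families} families of {lo}-{hi}")

    rng = np.random.default_rng(seed)
    sizes = rng.integers(lo, hi + 1, size=n_families)
    if total_size is not None:
        k = 0
        while sizes.sum() != total_size:
            step = 1 if sizes.sum() < total_size else -1
            j = k % n_families
            if lo <= sizes[j] + step <= hi:
                sizes[j] += step
            k += 1
    rows: list[tuple[str, str, str, str, str]] = []
    for f in range(n_families):
        fam = f"F{f + 1:03d}"
        size = int(sizes[f])
        counter = 0

        def new_id():
            nonlocal counter
            counter += 1
            return f"{fam}_I{counter:02d}"

        if size <= 4:
            for k in range(size):
                sex = "male" if k % 2 == 0 else "female"
                rows.append((fam, new_id(), MISSING_PARENT, MISSING_PARENT, sex))
            continue

        couples = []
        for _ in range(2):
            dad, mom = new_id(), new_id()
            rows.append((fam, dad, MISSING_PARENT, MISSING_PARENT, "male"))
            rows.append((fam, mom, MISSING_PARENT, MISSING_PARENT, "female"))
            couples.append((dad, mom))
        remaining = size - 4
        # first child of each founder couple; they mate to found generation 3
        c1 = c2 = None
        if remaining >= 1:
            c1 = new_id()
            rows.append((fam, c1, couples[0][0], couples[0][1], "male"))
            remaining -= 1
        if remaining >= 1:
            c2 = new_id()
            rows.append((fam, c2, couples[1][0], couples[1][1], "female"))
            remaining -= 1
        for _ in range(remaining):
            u = rng.random()
            sex = "female" if rng.random() < fraction_female else "male"
            child = new_id()
            if u < 0.4 or c2 is None:
                dad, mom = couples[0]
            elif u < 0.8:
                dad, mom = couples[1]
            else:
                dad, mom = c1, c2
            rows.append((fam, child, dad, mom, sex))

    ped = pd.DataFrame(rows, columns=PED_COLUMNS)
    validate_pedigree(ped)
    return ped


def write_ped(ped: pd.DataFrame, path) -> None:
    """Write PED-like whitespace-delimited text (0 = missing parent; sex 1/2)."""
    out = ped.copy()
    out["father_id"] = out["father_id"].replace(MISSING_PARENT, "0")
    out["mother_id"] = out["mother_id"].replace(MISSING_PARENT, "0")
    out["sex"] = out["sex"].map(_SEX_TO_PED)
    out.to_csv(path, sep=" ", header=False, index=False)


def read_ped(path) -> pd.DataFrame:
    ped = pd.read_csv(path, sep=r"\s+", header=None, names=PED_COLUMNS, dtype=str)
    ped["father_id"] = ped["father_id"].replace("0", MISSING_PARENT)
    ped["mother_id"] = ped["mother_id"].replace("0", MISSING_PARENT)
    ped["sex"] = ped["sex"].map(_PED_TO_SEX)
    validate_pedigree(ped)
    return ped
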