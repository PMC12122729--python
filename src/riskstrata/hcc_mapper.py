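"""Diagnosis-code to condition-category mapping with dominance hierarchies.

Hierarchical condition categories (HCCs) are binary diagnostic groupings in
which a more severe ("dominant") category suppresses related milder
("subordinate") ones: a beneficiary coded for both metastatic cancer and a
minor neoplasm counts only for the former.  This module provides a pluggable
mapping engine: a :class:`MappingTable` holds the code->category map and the
dominance rules, and can be loaded from CSV so licensed users may drop in the
real CMS tables.  A synthetic fixture table (79 categories, 2-5 codes each,
12 two-level dominance rules) is shipped for self-contained use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Conventional five-year age bands used for demographic cells; the top band
#: is open-ended.  Bands are closed on both ends.
AGE_BANDS: tuple[tuple[int, int | None], ...] = (
    (65, 69),
    (70, 74),
    (75, 79),
    (80, 84),
    (85, 89),
    (90, None),
)

SEXES = ("F", "M")


def demographic_cell(age: int, sex: str) -> str:
    """Return the (age-band, sex) cell id for an age at base-year start.

    Cells are labelled like ``"F_65_69"`` or ``"M_90plus"``.  Ages below 65
    are a caller error: the cohort filter is expected to have removed them.
    """
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}, got {sex!r}")
    if age < 65:
        raise ValueError(f"age {age} < 65: beneficiary should have been filtered out")
    for lo, hi in AGE_BANDS:
        if hi is None:
            return f"{sex}_{lo}plus"
        if lo <= age <= hi:
            return f"{sex}_{lo}_{hi}"
    raise AssertionError("unreachable")


def demographic_cell_ids() -> list[str]:
    """All cell ids, in lexicographic order (the design-matrix column order)."""
    cells = []
    for sex in SEXES:
        for lo, hi in AGE_BANDS:
            cells.append(f"{sex}_{lo}plus" if hi is None else f"{sex}_{lo}_{hi}")
    return sorted(cells)


@dataclass(frozen=True)
class MappingTable:
    """Code->category map plus dominance rules.

    Parameters
    ----------
    code_to_cc
        Diagnosis code string -> category id.
    hierarchy_rules
        Sequence of ``(dominant, (subordinate, ...))`` pairs: when the
        dominant category is present, every listed subordinate is zeroed.
    category_ids
        Ordered list of all category ids (the model's feature space, which
        may include categories never seen in the data).
    """

    code_to_cc: Mapping[str, str]
    hierarchy_rules: tuple[tuple[str, tuple[str, ...]], ...]
    category_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        known = set(self.category_ids)
        if len(known) != len(self.category_ids):
            raise ValueError("duplicate category ids")
        for code, cc in self.code_to_cc.items():
            if cc not in known:
                raise ValueError(f"code {code!r} maps to unknown category {cc!r}")
        for dom, subs in self.hierarchy_rules:
            for c in (dom, *subs):
                if c not in known:
                    raise ValueError(f"hierarchy rule references unknown category {c!r}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # DFS cycle detection on the dominant -> subordinate digraph.
        edges: dict[str, list[str]] = {}
        for dom, subs in self.hierarchy_rules:
            edges.setdefault(dom, []).extend(subs)
        WHITE, GREY, BLACK = 0, 1, 2
        colour = {c: WHITE for c in self.category_ids}

        def visit(node: str) -> None:
            colour[node] = GREY
            for nxt in edges.get(node, ()):
                if colour[nxt] == GREY:
                    raise ValueError(f"hierarchy rules contain a cycle through {nxt!r}")
                if colour[nxt] == WHITE:
                    visit(nxt)
            colour[node] = BLACK

        for c in self.category_ids:
            if colour[c] == WHITE:
                visit(c)

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_csv(cls, mapping_path, hierarchy_path=None) -> "MappingTable":
        """Load from ``mapping.csv`` (code, category) and ``hierarchy.csv``
        (dominant, subordinate); real CMS tables exported to this layout load
        the same way as the fixture."""
        mdf = pd.read_csv(mapping_path, dtype=str)
        code_to_cc = dict(zip(mdf["code"], mdf["category"]))
        rules: list[tuple[str, tuple[str, ...]]] = []
        if hierarchy_path is not None:
            hdf = pd.read_csv(hierarchy_path, dtype=str)
            for dom, grp in hdf.groupby("dominant", sort=True):
                rules.append((str(dom), tuple(sorted(grp["subordinate"]))))
        cats = sorted(set(code_to_cc.values()).union(
            c for dom, subs in rules for c in (dom, *subs)))
        return cls(code_to_cc, tuple(rules), tuple(cats))

    def to_csv(self, mapping_path, hierarchy_path) -> None:
        pd.DataFrame(
            sorted(self.code_to_cc.items()), columns=["code", "category"]
        ).to_csv(mapping_path, index=False)
        rows = [(dom, sub) for dom, subs in self.hierarchy_rules for sub in subs]
        pd.DataFrame(rows, columns=["dominant", "subordinate"]).to_csv(
            hierarchy_path, index=False
        )

    def codes_for(self, category: str) -> list[str]:
        return sorted(c for c, cc in self.code_to_cc.items() if cc == category)


def fixture_mapping_table(
    n_categories: int = 79, n_rules: int | None = None
) -> MappingTable:
    """Deterministic synthetic mapping table.

    Categories ``CC001..CC0nn`` each own 2-5 codes (``D001A``, ``D001B``, ...);
    the first ``2*n_rules`` categories form two-level dominance pairs
    (``CC001`` dominates ``CC002``, ``CC003`` dominates ``CC004``, ...).
    ``n_rules`` defaults to 12, reduced as needed for small tables.
    """
    if n_rules is None:
        n_rules = min(12, n_categories // 2)
    if n_categories < 2 * n_rules:
        raise ValueError("need at least 2 categories per hierarchy rule")
    cats = tuple(f"CC{i + 1:03d}" for i in range(n_categories))
    code_to_cc: dict[str, str] = {}
    sizes = (2, 3, 4, 5, 3)  # cycle; keeps the fixture irregular but reproducible
    for i, cat in enumerate(cats):
        for j in range(sizes[i % len(sizes)]):
            code_to_cc[f"D{i + 1:03d}{chr(ord('A') + j)}"] = cat
    rules = tuple((cats[2 * i], (cats[2 * i + 1],)) for i in range(n_rules))
    return MappingTable(code_to_cc, rules, cats)


# -- core operations -------------------------------------------------------


def map_to_categories(codes: Iterable[str], table: MappingTable) -> frozenset[str]:
    """Raw category set for a code list; unmapped codes are ignored."""
    out = set()
    for code in codes:
        cc = table.code_to_cc.get(code)
        if cc is None:
            logger.debug("unmapped diagnosis code %r ignored", code)
        else:
            out.add(cc)
    return frozenset(out)


def apply_hierarchy(raw: Iterable[str], table: MappingTable) -> frozenset[str]:
    """Zero subordinates of present dominants, simultaneously, to a fixed point.

    Each sweep removes every category subordinate to a dominant present in
    the *current* set; sweeps repeat until nothing changes.  The result is a
    subset of the input and the operation is idempotent.
    """
    current = set(raw)
    while True:
        doomed = {
            sub
            for dom, subs in table.hierarchy_rules
            if dom in current
            for sub in subs
            if sub in current
        }
        if not doomed:
            return frozenset(current)
        current -= doomed


def hierarchy_rule_indices(table: MappingTable) -> list[tuple[int, np.ndarray]]:
    """Rules as (dominant column index, subordinate column indices) pairs."""
    pos = {c: i for i, c in enumerate(table.category_ids)}
    return [
        (pos[dom], np.array([pos[s] for s in subs], dtype=np.intp))
        for dom, subs in table.hierarchy_rules
    ]


def apply_hierarchy_matrix(flags: np.ndarray, table: MappingTable) -> np.ndarray:
    """Vectorised :func:`apply_hierarchy` on an (n, k) boolean flag matrix.

    Modifies and returns a copy; columns follow ``table.category_ids``.
    """
    out = flags.copy()
    rules = hierarchy_rule_indices(table)
    changed = True
    while changed:
        changed = False
        snapshot = out.copy()
        for dom_ix, sub_ix in rules:
            mask = snapshot[:, dom_ix]
            if not mask.any():
                continue
            block = out[np.ix_(mask.nonzero()[0], sub_ix)]
            if block.any():
                out[np.ix_(mask.nonzero()[0], sub_ix)] = False
                changed = True
    return out


# -- profile construction --------------------------------------------------


def category_flag_matrix(
    claims: pd.DataFrame, ids: Sequence[str], year: int, table: MappingTable
) -> np.ndarray:
    """Post-hierarchy (n_ids, n_categories) boolean matrix from claim codes.

    Diagnosis codes from all claim settings (inpatient, outpatient, carrier)
    with ``service_year == year`` contribute.
    """
    ids = list(ids)
    id_pos = {b: i for i, b in enumerate(ids)}
    cat_pos = {c: j for j, c in enumerate(table.category_ids)}
    flags = np.zeros((len(ids), len(table.category_ids)), dtype=bool)

    sub = claims.loc[
        (claims["service_year"] == year) & (claims["diagnosis_codes"].astype(str) != ""),
        ["beneficiary_id", "diagnosis_codes"],
    ]
    sub = sub[sub["beneficiary_id"].isin(id_pos)]
    if len(sub):
        exploded = sub.assign(
            code=sub["diagnosis_codes"].str.split(";")
        ).explode("code")
        cat = exploded["code"].map(table.code_to_cc)
        n_unmapped = cat.isna().sum()
        if n_unmapped:
            logger.debug("%d unmapped diagnosis codes ignored", n_unmapped)
        exploded = exploded[cat.notna()]
        rows = exploded["beneficiary_id"].map(id_pos).to_numpy(dtype=np.intp)
        cols = cat[cat.notna()].map(cat_pos).to_numpy(dtype=np.intp)
        flags[rows, cols] = True
    return apply_hierarchy_matrix(flags, table)


def build_profiles(
    claims: pd.DataFrame,
    beneficiaries: pd.DataFrame,
    ids: Sequence[str],
    base_year: int,
    table: MappingTable,
) -> pd.DataFrame:
    """Per-beneficiary condition profiles for a base year.

    Returns a DataFrame with columns ``beneficiary_id``, ``base_year``,
    ``demographic_cell`` and ``hcc_flags`` (semicolon-joined, post-hierarchy),
    sorted by beneficiary id.
    """
    ids = sorted(ids)
    flags = category_flag_matrix(claims, ids, base_year, table)
    demo = (
        beneficiaries[["beneficiary_id", "sex", "birth_year"]]
        .drop_duplicates("beneficiary_id")
        .set_index("beneficiary_id")
        .loc[ids]
    )
    ages = base_year - demo["birth_year"].to_numpy()
    cells = [demographic_cell(int(a), s) for a, s in zip(ages, demo["sex"])]
    cats = np.array(table.category_ids)
    joined = [";".join(cats[row]) for row in flags]
    return pd.DataFrame(
        {
            "beneficiary_id": ids,
            "base_year": base_year,
            "demographic_cell": cells,
            "hcc_flags": joined,
        }
    )
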