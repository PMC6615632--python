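"""Genotype filtering, correction and imputation for recombinant lines.

Calls are coded ``A`` (ancestral), ``D`` (derived), ``H`` (heterozygous —
suspect in a haploid) and ``N`` (missing).  The pipeline order is fixed:

1. drop mutations invariant across all samples (artifactual assays);
2. drop mutations in complete linkage with the mating-type marker or a
   marker for an introgressed non-focal-background region;
3. correct single-working-primer mutations (missing -> nonamplified allele);
4. drop lines with >10% missing or >5% heterozygous calls (strict);
5. impute remaining missing calls, first from identical-haplotype lines of
   the same mating reaction, then from the adjacent mutation in genome order
   when pairwise LD satisfies r^2 > 0.7 (strict).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeTable",
    "QCReport",
    "drop_invariant_mutations",
    "drop_marker_linked_mutations",
    "correct_single_primer",
    "filter_lines",
    "set_het_missing",
    "ld_r_squared",
    "impute",
    "haplotype_summary",
    "run_qc",
]

CALLS = ("A", "D", "H", "N")


@dataclass
class GenotypeTable:
    """Calls (lines x sites) plus site and line metadata.

    ``sites`` is indexed by site id with columns ``chrom``, ``pos`` and
    boolean ``is_marker`` (mating-type / introgressed-region markers);
    annotation columns (snp_indel, location, ...) may follow.  ``lines`` is
    indexed by line id with optional ``mating_reaction`` and ``cross``
    columns.
    """

    calls: pd.DataFrame
    sites: pd.DataFrame
    lines: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not set(self.calls.columns) <= set(self.sites.index):
            raise ValueError("every call column needs a row in sites")
        bad = set(np.unique(self.calls.to_numpy())) - set(CALLS)
        if bad:
            raise ValueError(f"unknown call codes: {sorted(bad)}")
        if self.lines is None:
            self.lines = pd.DataFrame(index=self.calls.index)

    @property
    def mutation_ids(self) -> list:
        keep = self.sites.index[~self.sites["is_marker"]]
        return [c for c in self.calls.columns if c in set(keep)]

    @property
    def marker_ids(self) -> list:
        keep = self.sites.index[self.sites["is_marker"]]
        return [c for c in self.calls.columns if c in set(keep)]

    def copy(self) -> "GenotypeTable":
        return GenotypeTable(self.calls.copy(), self.sites.copy(), self.lines.copy())

    def binary(self, columns=None) -> pd.DataFrame:
        """0/1/NaN view (A=0, D=1, H and N = NaN)."""
        cols = self.calls if columns is None else self.calls[columns]
        return cols.apply(lambda c: c.map({"A": 0.0, "D": 1.0})).astype(float)


@dataclass
class QCReport:
    """Counts reconciling every pipeline stage."""

    mutations_in: int = 0
    mutations_invariant: int = 0
    mutations_marker_linked: int = 0
    lines_in: int = 0
    lines_removed_missing: int = 0
    lines_removed_het: int = 0
    cells_corrected: int = 0
    het_set_missing: int = 0
    cells_missing_initial: int = 0
    imputed_mating_reaction: int = 0
    imputed_ld: int = 0
    cells_missing_final: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


def drop_invariant_mutations(table: GenotypeTable) -> tuple[GenotypeTable, list]:
    """Remove mutation columns with a single non-missing call value."""
    removed = []
    for col in table.mutation_ids:
        vals = set(table.calls[col]) - {"N"}
        if len(vals) <= 1:
            removed.append(col)
    out = table.copy()
    out.calls = out.calls.drop(columns=removed)
    return out, removed


def _concordant(a: pd.Series, b: pd.Series) -> bool | None:
    """Perfect (anti-)concordance on pairwise-complete A/D calls.

    Returns None when there are no complete cases (no evidence either way).
    """
    ok = a.isin(["A", "D"]) & b.isin(["A", "D"])
    if not ok.any():
        return None
    same = (a[ok] == b[ok]).to_numpy()
    return bool(same.all() or (~same).all())


def drop_marker_linked_mutations(table: GenotypeTable) -> tuple[GenotypeTable, list]:
    """Remove mutations perfectly (anti-)concordant with any marker column."""
    markers = table.marker_ids
    removed = []
    for col in table.mutation_ids:
        for mk in markers:
            if _concordant(table.calls[col], table.calls[mk]):
                removed.append(col)
                break
    out = table.copy()
    out.calls = out.calls.drop(columns=removed)
    return out, removed


def correct_single_primer(
    table: GenotypeTable, affected: dict[str, str]
) -> tuple[GenotypeTable, int]:
    """Set missing calls to the nonamplified allele for listed mutations.

    One of the two allele-specific primers failed for these assays, so a
    missing call is evidence for the allele the working primer cannot
    amplify.  Only the listed mutations are touched.
    """
    out = table.copy()
    n = 0
    for col, allele in affected.items():
        if col not in out.calls.columns:
            raise KeyError(f"mutation {col!r} not present in table")
        if allele not in ("A", "D"):
            raise ValueError("nonamplified allele must be 'A' or 'D'")
        mask = out.calls[col] == "N"
        out.calls.loc[mask, col] = allele
        n += int(mask.sum())
    return out, n


def filter_lines(
    table: GenotypeTable, max_missing: float = 0.10, max_het: float = 0.05
) -> tuple[GenotypeTable, dict]:
    """Drop lines with strictly more than ``max_missing`` missing or
    ``max_het`` heterozygous mutation calls (fractions of mutation sites)."""
    muts = table.mutation_ids
    frac_missing = (table.calls[muts] == "N").mean(axis=1)
    frac_het = (table.calls[muts] == "H").mean(axis=1)
    drop_missing = frac_missing > max_missing
    drop_het = frac_het > max_het
    out = table.copy()
    keep = ~(drop_missing | drop_het)
    out.calls = out.calls.loc[keep]
    out.lines = out.lines.loc[keep]
    return out, {
        "removed_missing": int(drop_missing.sum()),
        "removed_het": int((drop_het & ~drop_missing).sum()),
    }


def set_het_missing(table: GenotypeTable) -> tuple[GenotypeTable, int]:
    """Recode surviving heterozygous calls as missing (haploid organism)."""
    out = table.copy()
    mask = out.calls == "H"
    out.calls = out.calls.mask(mask, "N")
    return out, int(mask.to_numpy().sum())


def ld_r_squared(col_a, col_b) -> float:
    """Haploid r^2 between two 0/1 call vectors on pairwise-complete cases.

    r^2 = (p_AB - p_A p_B)^2 / (p_A (1-p_A) p_B (1-p_B)); NaN when either
    column is monomorphic among complete cases.
    """
    a = np.asarray(col_a, dtype=float)
    b = np.asarray(col_b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size == 0:
        return float("nan")
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return float("nan")
    pab = (a * b).mean()
    d = pab - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def _ld_d(a: np.ndarray, b: np.ndarray) -> float:
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size == 0:
        return float("nan")
    return float((a * b).mean() - a.mean() * b.mean())


def impute(
    table: GenotypeTable, r2_threshold: float = 0.7
) -> tuple[GenotypeTable, dict]:
    """Two-step imputation of missing mutation calls.

    Step 1 (mating reaction): a missing call is filled from another line of
    the same mating reaction whose calls match at all co-called mutation
    sites (strict identity) and which is called at the missing site; if
    candidate donors disagree, the cell stays missing.

    Step 2 (LD): a still-missing call is filled from the adjacent mutation in
    chromosome/position order (never across chromosomes) when pairwise
    r^2 > ``r2_threshold`` (strict); with two qualifying neighbours the
    higher-r^2 one is used, ties going upstream.  The imputed state follows
    the phase implied by the sign of D.  r^2 and D are computed once on the
    step-2 input, so fills do not cascade within the step.
    """
    out = table.copy()
    muts = out.mutation_ids
    n_step1 = 0
    if "mating_reaction" in out.lines.columns:
        calls = out.calls
        for reaction, group in out.lines.groupby("mating_reaction"):
            ids = list(group.index)
            if len(ids) < 2:
                continue
            sub = calls.loc[ids, muts]
            for line in ids:
                row = sub.loc[line]
                miss = row.index[row == "N"]
                if not len(miss):
                    continue
                for other in ids:
                    if other == line:
                        continue
                    orow = sub.loc[other]
                    both = (row != "N") & (orow != "N")
                    if not (row[both] == orow[both]).all():
                        continue
                    for site in list(miss):
                        donor = orow[site]
                        if donor == "N":
                            continue
                        cur = out.calls.at[line, site]
                        if cur == "N":
                            out.calls.at[line, site] = donor
                            n_step1 += 1
                        elif cur != donor:  # donor conflict: revert
                            out.calls.at[line, site] = "N"
                            n_step1 -= 1
    # --- step 2: LD with the genome-order neighbour
    n_step2 = 0
    binary = out.binary(muts)
    order = (
        out.sites.loc[muts]
        .sort_values(["chrom", "pos"])
        .index.tolist()
    )
    pos_in_order = {site: i for i, site in enumerate(order)}
    chrom = out.sites["chrom"]
    fills: list[tuple] = []
    for site in muts:
        col = binary[site].to_numpy()
        missing_lines = out.calls.index[out.calls[site] == "N"]
        if not len(missing_lines):
            continue
        i = pos_in_order[site]
        neighbours = []
        for j in (i - 1, i + 1):  # upstream first (tie preference)
            if 0 <= j < len(order) and chrom[order[j]] == chrom[site]:
                nb = order[j]
                r2 = ld_r_squared(col, binary[nb].to_numpy())
                if np.isfinite(r2) and r2 > r2_threshold:
                    neighbours.append((r2, j != i - 1, nb))
        if not neighbours:
            continue
        neighbours.sort(key=lambda x: (-x[0], x[1]))
        r2, _, nb = neighbours[0]
        d = _ld_d(col, binary[nb].to_numpy())
        for line in missing_lines:
            nb_call = out.calls.at[line, nb]
            if nb_call not in ("A", "D"):
                continue
            nb_state = 1.0 if nb_call == "D" else 0.0
            state = nb_state if d > 0 else 1.0 - nb_state
            fills.append((line, site, "D" if state == 1.0 else "A"))
    for line, site, call in fills:
        out.calls.at[line, site] = call
        n_step2 += 1
    return out, {"imputed_mating_reaction": n_step1, "imputed_ld": n_step2}


def haplotype_summary(table: GenotypeTable, by_cross: bool = False) -> dict:
    """Distinct haplotypes, their multiplicities and derived-allele content.

    A haplotype is the full vector of mutation calls for a line; identical
    vectors (within a cross when ``by_cross``) define one haplotype.  The
    derived proportion per haplotype is the fraction of derived calls among
    non-missing mutation calls.
    """
    muts = table.mutation_ids
    calls = table.calls[muts]
    if by_cross and "cross" in table.lines.columns:
        keys = table.lines["cross"].astype(str) + "|" + calls.agg("".join, axis=1)
    else:
        keys = calls.agg("".join, axis=1)
    groups = keys.groupby(keys).size()
    derived = {}
    for hap in groups.index:
        vec = hap.split("|")[-1]
        called = [c for c in vec if c in ("A", "D")]
        derived[hap] = (
            sum(c == "D" for c in called) / len(called) if called else float("nan")
        )
    props = pd.Series(derived)
    return {
        "n_haplotypes": int(len(groups)),
        "multiplicity": groups.sort_values(ascending=False),
        "derived_proportion": props,
        "mean_derived_proportion": float(np.nanmean(props.to_numpy())),
    }


def run_qc(
    table: GenotypeTable,
    single_primer: dict[str, str] | None = None,
    max_missing: float = 0.10,
    max_het: float = 0.05,
    r2_threshold: float = 0.7,
) -> tuple[GenotypeTable, QCReport]:
    """Full pipeline in the fixed stage order; counts reconcile per stage."""
    rep = QCReport(
        mutations_in=len(table.mutation_ids), lines_in=len(table.calls.index)
    )
    table, inv = drop_invariant_mutations(table)
    rep.mutations_invariant = len(inv)
    table, linked = drop_marker_linked_mutations(table)
    rep.mutations_marker_linked = len(linked)
    if single_primer:
        present = {k: v for k, v in single_primer.items() if k in table.calls.columns}
        table, rep.cells_corrected = correct_single_primer(table, present)
    table, line_rep = filter_lines(table, max_missing=max_missing, max_het=max_het)
    rep.lines_removed_missing = line_rep["removed_missing"]
    rep.lines_removed_het = line_rep["removed_het"]
    table, rep.het_set_missing = set_het_missing(table)
    muts = table.mutation_ids
    rep.cells_missing_initial = int((table.calls[muts] == "N").to_numpy().sum())
    table, imp = impute(table, r2_threshold=r2_threshold)
    rep.imputed_mating_reaction = imp["imputed_mating_reaction"]
    rep.imputed_ld = imp["imputed_ld"]
    rep.cells_missing_final = int((table.calls[muts] == "N").to_numpy().sum())
    return table, rep
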