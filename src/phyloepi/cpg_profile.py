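"""Dinucleotide site scanning, conservation classification and divergence stats.

A *dinucleotide site* is an ordered pair of adjacent alignment columns. CpG
dinucleotides are the substrate of vertebrate DNA methylation, and methylated
CpGs decay towards TpG via deamination of 5-methylcytosine at a strongly
elevated transition rate, so their conservation pattern across closely related
species carries a signal distinct from ordinary nucleotide divergence. This
module finds the sites "belonging to" a dinucleotide type under a configurable
preservation rule, classifies each by conservation, and summarises divergence:

* ``polymorphic_column_fraction`` — share of alignment columns where at least
  two distinct non-gap states occur (the SNP-level divergence of the region);
* per dinucleotide type, the number of preserved sites, how many of them are
  altered in at least one taxon, the altered share of preserved sites, and the
  altered sites as a fraction of all alignment columns.

The preservation rule formalises "largely preserved across taxa": by default a
site counts as belonging to a type when a strict majority of taxa show that
dinucleotide at the column pair (``majority``). ``reference_taxon:<label>``
and ``any`` are available where an asymmetric or permissive notion is wanted.

Denominator conventions (documented prominently because the choice matters
when comparing against published percentages): ``genome_fraction`` counts
altered *sites* (column pairs) in the numerator and alignment *columns* in the
denominator; sites containing gaps or N in any taxon are excluded from all
numerators but columns stay in the denominator.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .errors import ParameterError
from .msa_io import GAP_CHARS, AlignedSeqSet

_DNA = frozenset("ACGT")

#: The dinucleotide types the divergence contrast is usually run over.
DEFAULT_DINUC_TYPES = ("CG", "AG", "TG", "GG")


class SiteClass(str, Enum):
    """Conservation class of a dinucleotide site.

    ``NOT_PRESERVED`` marks a site failing the preservation rule; the scanner
    does not report such sites, so it only appears when classifying arbitrary
    column pairs directly.
    """

    CONSERVED_ALL = "conserved_all"
    PRESERVED_VARIABLE = "preserved_variable"
    NOT_PRESERVED = "not_preserved"
    GAPPED = "gapped"


@dataclass(frozen=True)
class DinucSite:
    """One dinucleotide locus: alignment columns ``[column, column+2)``."""

    column: int
    dinuc_type: str
    states: "dict[str, str]"  # taxon label -> observed dinucleotide
    site_class: SiteClass


@dataclass(frozen=True)
class DinucTypeStats:
    """Divergence summary for one dinucleotide type."""

    dinuc_type: str
    n_preserved_sites: int
    n_preserved_variable_sites: int
    preserved_variable_fraction: float  # variable / preserved (0 if none)
    genome_fraction: float  # variable sites / alignment columns


@dataclass(frozen=True)
class DivergenceStats:
    """Alignment-wide divergence statistics."""

    n_columns: int
    polymorphic_column_fraction: float
    per_dinuc: "dict[str, DinucTypeStats]"

    def to_frame(self) -> pd.DataFrame:
        """Per-type statistics as a DataFrame (one row per dinucleotide type)."""
        rows = []
        for st in self.per_dinuc.values():
            rows.append(
                {
                    "dinuc_type": st.dinuc_type,
                    "n_preserved_sites": st.n_preserved_sites,
                    "n_preserved_variable_sites": st.n_preserved_variable_sites,
                    "preserved_variable_fraction": st.preserved_variable_fraction,
                    "genome_fraction": st.genome_fraction,
                    "n_columns": self.n_columns,
                    "polymorphic_column_fraction": self.polymorphic_column_fraction,
                }
            )
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        d = {
            "n_columns": self.n_columns,
            "polymorphic_column_fraction": self.polymorphic_column_fraction,
            "dinuc": {},
        }
        for name, st in self.per_dinuc.items():
            d["dinuc"][name] = {
                "n_preserved_sites": st.n_preserved_sites,
                "n_preserved_variable_sites": st.n_preserved_variable_sites,
                "preserved_variable_fraction": st.preserved_variable_fraction,
                "genome_fraction": st.genome_fraction,
            }
        return d


def _check_dinuc_type(dinuc_type: str) -> str:
    dt = str(dinuc_type).upper()
    if len(dt) != 2 or any(c not in _DNA for c in dt):
        raise ParameterError(f"invalid dinucleotide type {dinuc_type!r}")
    return dt


def _parse_rule(aln: AlignedSeqSet, reference_rule: str):
    """Return ("majority"|"any"|"reference", taxon_index_or_None)."""
    rule = str(reference_rule)
    if rule == "majority":
        return "majority", None
    if rule == "any":
        return "any", None
    for prefix in ("reference_taxon:", "reference:"):
        if rule.startswith(prefix):
            label = rule[len(prefix):]
            if label not in aln.labels:
                raise ParameterError(
                    f"reference taxon {label!r} not in alignment labels"
                )
            return "reference", aln.labels.index(label)
    raise ParameterError(f"unknown reference rule {reference_rule!r}")


def _byte_matrix(aln: AlignedSeqSet) -> np.ndarray:
    """(n_taxa, length) uint8 view of the alignment."""
    return np.frombuffer("".join(aln.rows).encode("ascii"), dtype=np.uint8).reshape(
        aln.n_taxa, aln.length
    )


def classify_state_pattern(
    states: "dict[str, str]", dinuc_type: str, preserved: bool = True
) -> SiteClass:
    """Classify one site's per-taxon dinucleotide states.

    Precedence: any gap/N in either position -> GAPPED; all states equal to the
    type -> CONSERVED_ALL; otherwise PRESERVED_VARIABLE if the site passed the
    preservation rule (*preserved*), else NOT_PRESERVED.
    """
    dt = _check_dinuc_type(dinuc_type)
    vals = list(states.values())
    if any(c in GAP_CHARS for s in vals for c in s):
        return SiteClass.GAPPED
    if all(s == dt for s in vals):
        return SiteClass.CONSERVED_ALL
    return SiteClass.PRESERVED_VARIABLE if preserved else SiteClass.NOT_PRESERVED


def scan_dinuc_sites(
    aln: AlignedSeqSet,
    dinuc_type: str = "CG",
    reference_rule: str = "majority",
) -> "list[DinucSite]":
    """Find and classify all sites of *dinuc_type* under *reference_rule*.

    A column pair ``[i, i+2)`` is reported when it belongs to the type under
    the rule: ``majority`` — a strict majority of taxa show the dinucleotide;
    ``any`` — at least one taxon does; ``reference_taxon:<label>`` — that
    taxon does. Overlapping sites (e.g. both CGs of ``CGCG``) are all
    reported. Sites failing the rule are not reported.
    """
    dt = _check_dinuc_type(dinuc_type)
    kind, ref_idx = _parse_rule(aln, reference_rule)
    M = _byte_matrix(aln)
    first, second = M[:, :-1], M[:, 1:]
    a, b = (ord(c) for c in dt)
    is_type = (first == a) & (second == b)  # (n_taxa, L-1)
    if kind == "majority":
        candidate = is_type.sum(axis=0) * 2 > aln.n_taxa
    elif kind == "any":
        candidate = is_type.any(axis=0)
    else:
        candidate = is_type[ref_idx]

    gap_codes = np.frombuffer("".join(sorted(GAP_CHARS)).encode(), dtype=np.uint8)
    is_gap = np.isin(first, gap_codes) | np.isin(second, gap_codes)
    site_gapped = is_gap.any(axis=0)
    all_type = is_type.all(axis=0)

    sites: list[DinucSite] = []
    for i in np.flatnonzero(candidate):
        i = int(i)
        states = {lab: row[i : i + 2] for lab, row in zip(aln.labels, aln.rows)}
        if site_gapped[i]:
            cls = SiteClass.GAPPED
        elif all_type[i]:
            cls = SiteClass.CONSERVED_ALL
        else:
            cls = SiteClass.PRESERVED_VARIABLE
        sites.append(DinucSite(i, dt, states, cls))
    return sites


def classify_sites(sites: "list[DinucSite]") -> "dict[SiteClass, int]":
    """Partition counts by conservation class (all four classes always keyed).

    A preserved-variable site counts once no matter how many taxa or how many
    of its two positions differ from the reference dinucleotide.
    """
    counts = Counter(site.site_class for site in sites)
    return {cls: counts.get(cls, 0) for cls in SiteClass}


def polymorphic_column_fraction(aln: AlignedSeqSet) -> float:
    """Fraction of columns with >= 2 distinct non-gap states among taxa.

    Gap-only columns and columns with a single residue state (however many
    gaps) are not polymorphic. The denominator is all alignment columns.
    """
    M = _byte_matrix(aln)
    gap_codes = np.frombuffer("".join(sorted(GAP_CHARS)).encode(), dtype=np.uint8)
    valid = ~np.isin(M, gap_codes)
    # A column is polymorphic iff two valid entries differ.
    n_poly = 0
    masked = np.where(valid, M, 0)
    first_valid = valid.argmax(axis=0)  # index of first non-gap row (if any)
    any_valid = valid.any(axis=0)
    ref = masked[first_valid, np.arange(aln.length)]
    differs = valid & (M != ref[None, :])
    n_poly = int((differs.any(axis=0) & any_valid).sum())
    return n_poly / aln.length


def dinuc_divergence_stats(
    aln: AlignedSeqSet,
    dinuc_types: "tuple[str, ...]" = DEFAULT_DINUC_TYPES,
    reference_rule: str = "majority",
) -> DivergenceStats:
    """Scan + classify every requested dinucleotide type and summarise.

    ``n_preserved_sites`` counts gap-free rule-passing sites (conserved plus
    variable); gapped sites are excluded from all numerators. Fractions over
    an empty preserved set are defined as 0.
    """
    per: dict[str, DinucTypeStats] = {}
    for dt in dinuc_types:
        dt = _check_dinuc_type(dt)
        counts = classify_sites(scan_dinuc_sites(aln, dt, reference_rule))
        n_cons = counts[SiteClass.CONSERVED_ALL]
        n_var = counts[SiteClass.PRESERVED_VARIABLE]
        n_pres = n_cons + n_var
        per[dt] = DinucTypeStats(
            dinuc_type=dt,
            n_preserved_sites=n_pres,
            n_preserved_variable_sites=n_var,
            preserved_variable_fraction=(n_var / n_pres) if n_pres else 0.0,
            genome_fraction=n_var / aln.length,
        )
    return DivergenceStats(
        n_columns=aln.length,
        polymorphic_column_fraction=polymorphic_column_fraction(aln),
        per_dinuc=per,
    )


def site_table(sites: "list[DinucSite]") -> pd.DataFrame:
    """Per-site report: column, type, class, then one state column per taxon."""
    if not sites:
        return pd.DataFrame(columns=["column", "dinuc_type", "site_class"])
    taxa = list(sites[0].states)
    rows = []
    for s in sites:
        row = {
            "column": s.column,
            "dinuc_type": s.dinuc_type,
            "site_class": s.site_class.value,
        }
        for t in taxa:
            row[t] = s.states[t]
        rows.append(row)
    return pd.DataFrame(rows)
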