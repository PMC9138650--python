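"""Binary epigenetic recoding of preserved CpG sites.

Each taxon receives one character per admitted CpG site: ``A`` if its
dinucleotide at the site is exactly ``CG`` (the CpG is intact and therefore a
potential methylation substrate), ``T`` if it is mutated in one or both
positions. The assignment is made per taxon — every species gets its own A/T
at each site — so the matrix captures *which* lineages have lost which CpGs,
and clustering the strings groups taxa by shared CpG retention. Sites come
from the shared alignment coordinate frame, so the recoded characters are
already positionally homologous and no realignment is performed.

Constant all-``A`` columns (CpG intact in every taxon) are kept by default;
they dilute all pairwise distances uniformly and cannot change an
average-linkage topology, and dropping them is available via
``include_constant=False`` for a matrix of variable sites only.
"""
from __future__ import annotations

import os
from dataclasses import dataclass

import pandas as pd

from .cpg_profile import DinucSite, SiteClass
from .errors import RecodingError
from .msa_io import AlignedSeqSet


@dataclass(frozen=True)
class EpiMatrix:
    """Per-taxon binary character strings over preserved CpG sites.

    ``characters[k][j]`` is the A/T state of taxon ``labels[k]`` at the site
    starting at alignment column ``site_index[j]``.
    """

    labels: tuple[str, ...]
    characters: tuple[str, ...]
    site_index: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "characters", tuple(self.characters))
        object.__setattr__(self, "site_index", tuple(int(i) for i in self.site_index))
        n = len(self.site_index)
        if len(self.labels) != len(self.characters):
            raise RecodingError("labels/characters length mismatch")
        for lab, chars in zip(self.labels, self.characters):
            if len(chars) != n:
                raise RecodingError(
                    f"taxon {lab!r} has {len(chars)} characters for {n} sites"
                )
            if set(chars) - {"A", "T"}:
                raise RecodingError(f"taxon {lab!r} has characters outside A/T")
        if list(self.site_index) != sorted(set(self.site_index)):
            raise RecodingError("site_index must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return len(self.site_index)

    @property
    def is_degenerate(self) -> bool:
        """True when no characters remain (no informative CpG sites)."""
        return self.n_sites == 0

    def to_frame(self) -> pd.DataFrame:
        """Sites as columns (named by alignment column), taxa as rows."""
        return pd.DataFrame(
            [list(c) for c in self.characters],
            index=list(self.labels),
            columns=[str(i) for i in self.site_index],
        )

    def to_fasta(self, path: "str | os.PathLike") -> None:
        """Write the A/T strings as FASTA (consumable by aligners or phylo)."""
        with open(os.fspath(path), "w") as fh:
            for lab, chars in zip(self.labels, self.characters):
                fh.write(f">{lab}\n{chars}\n")


def recode_cpg_matrix(
    aln: AlignedSeqSet,
    sites: "list[DinucSite]",
    include_constant: bool = True,
) -> EpiMatrix:
    """Recode preserved CpG sites into an :class:`EpiMatrix`.

    *sites* must be gap-free CG sites scanned from *aln* (classes
    ``conserved_all`` or ``preserved_variable``); a gapped site or a site whose
    taxa differ from the alignment's raises :class:`RecodingError`. With
    ``include_constant=False``, all-``A`` (conserved) columns are dropped.
    """
    aln_labels = set(aln.labels)
    admitted: list[DinucSite] = []
    ref_type = None
    for site in sites:
        if site.site_class is SiteClass.GAPPED:
            raise RecodingError(
                f"gapped site at column {site.column} cannot be recoded; "
                "exclude gapped sites upstream"
            )
        if site.site_class is SiteClass.NOT_PRESERVED:
            raise RecodingError(
                f"site at column {site.column} failed the preservation rule"
            )
        if set(site.states) != aln_labels:
            raise RecodingError(
                f"site at column {site.column} references taxa "
                f"{sorted(set(site.states) ^ aln_labels)} inconsistent with alignment"
            )
        if ref_type is None:
            ref_type = site.dinuc_type
        elif site.dinuc_type != ref_type:
            raise RecodingError("sites mix different dinucleotide types")
        if include_constant or site.site_class is not SiteClass.CONSERVED_ALL:
            admitted.append(site)
    admitted.sort(key=lambda s: s.column)
    characters = tuple(
        "".join(
            "A" if site.states[lab] == site.dinuc_type else "T" for site in admitted
        )
        for lab in aln.labels
    )
    return EpiMatrix(aln.labels, characters, tuple(s.column for s in admitted))
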