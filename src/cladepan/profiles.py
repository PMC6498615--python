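"""Clade-level gene-content profiling from the ternary presence matrix.

Covers four questions a comparative-genomics study asks once clades are
known: which families are diagnostic of a clade, which contiguous CDS runs
of one genome are absent from a comparison group (variable regions / regions
of genomic plasticity), how complete the strains' metabolic pathways are,
and how many components of each phosphotransferase system (PTS) each strain
carries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import ABSENT, FRAGMENT, INTACT, CladepanError, GeneAnnotation, TernaryMatrix


@dataclass
class PathwayDef:
    """A pathway as an ordered list of required gene-family roles."""

    pathway_id: str
    name: str
    roles: list[str]

    def __post_init__(self) -> None:
        if not self.roles:
            raise CladepanError(f"pathway {self.pathway_id!r} has no roles")
        if len(set(self.roles)) != len(self.roles):
            raise CladepanError(f"pathway {self.pathway_id!r} has duplicate roles")


@dataclass
class PtsDef:
    """A PTS sugar-uptake system with 1-4 EII component families."""

    system_id: str
    substrate: str
    components: list[str]

    def __post_init__(self) -> None:
        if not 1 <= len(self.components) <= 4:
            raise CladepanError(
                f"PTS {self.system_id!r} must have 1-4 components, "
                f"got {len(self.components)}"
            )


@dataclass
class RegionReport:
    """Variable regions of one genome relative to a comparison group."""

    genome_id: str
    regions: list[tuple[str, int, int, int]]  # (contig, start, end, n_cds)
    n_regions: int
    total_bp: int
    total_cds: int

    def __post_init__(self) -> None:
        if self.n_regions != len(self.regions):
            raise CladepanError("region count does not match region list")
        if self.total_bp != sum(r[2] - r[1] + 1 for r in self.regions):
            raise CladepanError("total bp does not match region spans")
        if self.total_cds != sum(r[3] for r in self.regions):
            raise CladepanError("total CDS does not match region CDS counts")


def _presence(matrix: TernaryMatrix, mode: str) -> pd.DataFrame:
    if mode == "any":
        return matrix.df >= FRAGMENT
    if mode == "intact_only":
        return matrix.df == INTACT
    raise CladepanError(f"unknown presence mode {mode!r}")


def clade_specific_families(
    matrix: TernaryMatrix,
    clade_of: dict[str, str],
    min_in: float = 0.90,
    max_out: float = 0.05,
    presence: str = "any",
) -> dict[str, set[str]]:
    """Families present in >= min_in of a clade and <= max_out outside it."""
    for t in (min_in, max_out):
        if not 0.0 <= t <= 1.0:
            raise CladepanError(f"threshold {t} outside [0, 1]")
    missing = [g for g in matrix.genomes if g not in clade_of]
    if missing:
        raise CladepanError(f"genomes without a clade label: {missing}")
    present = _presence(matrix, presence)
    clades = sorted(set(clade_of.values()))
    out: dict[str, set[str]] = {c: set() for c in clades}
    for clade in clades:
        in_rows = [g for g in matrix.genomes if clade_of[g] == clade]
        out_rows = [g for g in matrix.genomes if clade_of[g] != clade]
        frac_in = present.loc[in_rows].mean(axis=0)
        frac_out = (
            present.loc[out_rows].mean(axis=0)
            if out_rows
            else pd.Series(0.0, index=present.columns)
        )
        hits = present.columns[(frac_in >= min_in) & (frac_out <= max_out)]
        out[clade] = set(map(str, hits))
    return out


def detect_variable_regions(
    target_annotations: list[GeneAnnotation],
    matrix: TernaryMatrix,
    other_group: list[str],
    family_of: dict[str, str],
    min_run: int = 5,
    gap_tolerance: int = 0,
    presence: str = "any",
) -> RegionReport:
    """Maximal runs of CDS whose families are absent from every genome of the
    comparison group.

    CDS are walked per contig in coordinate order; a region needs at least
    ``min_run`` marked CDS and may bridge up to ``gap_tolerance`` unmarked
    interior CDS.  Region span is last CDS end - first CDS start + 1.
    """
    if not other_group:
        raise CladepanError("comparison group is empty")
    unknown = [g for g in other_group if g not in matrix.genomes]
    if unknown:
        raise CladepanError(f"comparison genomes not in matrix: {unknown}")
    if not target_annotations:
        raise CladepanError("target genome has no annotations")
    genome_id = target_annotations[0].genome_id
    present = _presence(matrix, presence).loc[other_group]
    absent_everywhere = ~present.any(axis=0)

    def marked(a: GeneAnnotation) -> bool:
        fam = family_of.get(a.gene_id)
        if fam is None or fam not in absent_everywhere.index:
            return False
        return bool(absent_everywhere[fam])

    regions: list[tuple[str, int, int, int]] = []
    by_contig: dict[str, list[GeneAnnotation]] = {}
    for a in sorted(target_annotations, key=lambda x: (x.contig_id, x.start)):
        by_contig.setdefault(a.contig_id, []).append(a)
    for contig, anns in by_contig.items():
        flags = [marked(a) for a in anns]
        i = 0
        n = len(anns)
        while i < n:
            if not flags[i]:
                i += 1
                continue
            # grow a run allowing <= gap_tolerance unmarked interior CDS
            j = i
            gaps = 0
            last_marked = i
            k = i + 1
            while k < n:
                if flags[k]:
                    last_marked = k
                    k += 1
                else:
                    # count the prospective interior gap
                    run_gaps = gaps + 1
                    if run_gaps > gap_tolerance:
                        break
                    gaps = run_gaps
                    k += 1
            j = last_marked
            n_marked = sum(1 for t in range(i, j + 1) if flags[t])
            if n_marked >= min_run:
                regions.append(
                    (contig, anns[i].start, anns[j].end, j - i + 1)
                )
            i = j + 1
    regions.sort(key=lambda r: (r[0], r[1]))
    return RegionReport(
        genome_id=genome_id,
        regions=regions,
        n_regions=len(regions),
        total_bp=sum(r[2] - r[1] + 1 for r in regions),
        total_cds=sum(r[3] for r in regions),
    )


def _resolve(labels: list[str], matrix: TernaryMatrix, context: str) -> list[str | None]:
    resolved: list[str | None] = []
    known = set(matrix.families)
    for lab in labels:
        if lab in known:
            resolved.append(lab)
        else:
            warnings.warn(f"{context}: family {lab!r} not in matrix; counted absent",
                          stacklevel=3)
            resolved.append(None)
    return resolved


def pathway_completion(
    matrix: TernaryMatrix,
    pathways: list[PathwayDef],
    presence: str = "intact_only",
) -> pd.DataFrame:
    """Strain x pathway completion fractions (roles present / roles)."""
    if not pathways:
        raise CladepanError("no pathways given")
    present = _presence(matrix, presence)
    out = pd.DataFrame(index=matrix.genomes, dtype=float)
    for pw in pathways:
        roles = _resolve(pw.roles, matrix, f"pathway {pw.pathway_id}")
        hit = np.zeros(len(matrix.genomes))
        for role in roles:
            if role is not None:
                hit += present[role].to_numpy()
        out[pw.pathway_id] = hit / len(pw.roles)
    return out


def pts_component_counts(
    matrix: TernaryMatrix,
    systems: list[PtsDef],
    presence: str = "intact_only",
) -> pd.DataFrame:
    """Strain x PTS integer component counts (0 to |components|)."""
    if not systems:
        raise CladepanError("no PTS systems given")
    present = _presence(matrix, presence)
    out = pd.DataFrame(index=matrix.genomes, dtype=int)
    for sys_def in systems:
        comps = _resolve(sys_def.components, matrix, f"PTS {sys_def.system_id}")
        count = np.zeros(len(matrix.genomes), dtype=int)
        for comp in comps:
            if comp is not None:
                count += present[comp].to_numpy().astype(int)
        out[sys_def.system_id] = count
    return out


def gene_status_report(
    matrix: TernaryMatrix,
    family_labels: list[str],
    strain_order: list[str] | None = None,
) -> pd.DataFrame:
    """Slice of the ternary matrix in requested row/column order.

    Unresolvable family labels become all-absent columns with a warning.
    States: 0 absent, 1 fragment-only, 2 intact.
    """
    strains = strain_order if strain_order is not None else matrix.genomes
    unknown = [s for s in strains if s not in matrix.genomes]
    if unknown:
        raise CladepanError(f"unknown strains: {unknown}")
    out = pd.DataFrame(index=strains, dtype=int)
    for lab in family_labels:
        if lab in matrix.df.columns:
            out[lab] = matrix.df.loc[strains, lab].astype(int)
        else:
            warnings.warn(f"family {lab!r} not in matrix; all-absent column",
                          stacklevel=2)
            out[lab] = 0
    return out
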