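"""Post-processing of phosphosite and interaction-enrichment tables.

Implements the site-table operations downstream of the search engine:
abundance normalization, the high-confidence filter (present in >= 3 of 4
replicates with localization probability strictly above 0.75, evaluated per
protein variant), symmetric log2-fold-change enrichment between phospho- and
non-phospho-column eluates, PKA consensus motif scanning, and cross-species
conservation ratios from a pre-computed multiple alignment.

Site tables are plain DataFrames with columns ``protein_id``, ``variant``,
``residue`` (S/T/Y), ``position`` (1-based), ``localization_prob`` and
``intensity_rep<k>`` / ``protein_abundance_rep<k>`` per replicate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import AlignIO

__all__ = [
    "MotifHit",
    "ConservationRecord",
    "normalize_site_intensities",
    "high_confidence_filter",
    "enrichment_filter",
    "pka_motif_scan",
    "conservation_ratio",
    "DEFAULT_PKA_CONSENSUS",
]

# Minimal PKA consensus set: basic residues N-terminal of the S/T acceptor.
# Chosen to recover the canonical R-R-x-S/T site and the K-R-x-S arrangement
# of the S351 peptide (LKRASVDVDLLA).
DEFAULT_PKA_CONSENSUS = ("[RK][RK].[ST]", "[RK]..[ST]")

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")

# physicochemical classes used to report conservative substitutions
_CONSERVATIVE_GROUPS = [set("ST"), set("DE"), set("KR"), set("ILVM"), set("FYW"), set("NQ")]


def _replicate_columns(table: pd.DataFrame, prefix: str) -> list[str]:
    cols = sorted(
        (c for c in table.columns if re.fullmatch(rf"{prefix}_rep\d+", c)),
        key=lambda c: int(c.rsplit("rep", 1)[1]),
    )
    if not cols:
        raise ValueError(f"no {prefix}_rep<k> columns found")
    return cols


def normalize_site_intensities(sites: pd.DataFrame) -> pd.DataFrame:
    """Divide each site intensity by the protein abundance of its replicate.

    Missing intensities stay missing. A zero or missing abundance paired
    with a present intensity is an error (the ratio would be undefined).
    """
    intensity_cols = _replicate_columns(sites, "intensity")
    abundance_cols = _replicate_columns(sites, "protein_abundance")
    if len(intensity_cols) != len(abundance_cols):
        raise ValueError("intensity and abundance replicate structure differ")
    out = sites.copy()
    for icol, acol in zip(intensity_cols, abundance_cols):
        intensity = out[icol].to_numpy(dtype=float)
        abundance = out[acol].to_numpy(dtype=float)
        present = ~np.isnan(intensity)
        bad = present & (np.isnan(abundance) | (abundance <= 0))
        if bad.any():
            raise ValueError("zero or missing protein abundance for a measured intensity")
        out[icol] = intensity / abundance
    return out


def high_confidence_filter(
    sites: pd.DataFrame,
    min_replicates: int = 3,
    total_replicates: int = 4,
    min_loc_prob: float = 0.75,
) -> pd.DataFrame:
    """Keep high-confidence phosphosites, evaluated per protein variant.

    A site passes for a variant when its intensity is non-missing in at
    least ``min_replicates`` of ``total_replicates`` replicates *and* its
    localization probability strictly exceeds ``min_loc_prob`` (a site at
    exactly 0.75 is dropped). The result is the union across variants, one
    row per (protein, position), with per-variant pass flags and a
    ``variant_class`` of ``unique_to_<v>`` or ``both``.
    """
    intensity_cols = _replicate_columns(sites, "intensity")[:total_replicates]
    present = sites[intensity_cols].notna().sum(axis=1)
    passing = sites[(present >= min_replicates) & (sites["localization_prob"] > min_loc_prob)]
    if passing.empty:
        return passing.assign(variant_class=pd.Series(dtype=str))

    variants = list(dict.fromkeys(sites.get("variant", pd.Series(["all"])).tolist()))
    rows = []
    for (protein, position), grp in passing.groupby(["protein_id", "position"], sort=True):
        present_variants = sorted(set(grp["variant"])) if "variant" in grp else ["all"]
        if len(present_variants) > 1:
            variant_class = "both" if len(variants) == 2 else "multiple"
        else:
            variant_class = f"unique_to_{present_variants[0]}" if len(variants) > 1 else "all"
        first = grp.iloc[0]
        row = {
            "protein_id": protein,
            "position": position,
            "residue": first["residue"],
            "localization_prob": float(grp["localization_prob"].max()),
            "variants": ";".join(present_variants),
            "variant_class": variant_class,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def enrichment_filter(
    records: pd.DataFrame,
    min_valid_per_group: int = 2,
    fc_threshold: float = 2.0,
    group_col: str = "group",
    value_cols: list[str] | None = None,
) -> dict:
    """Two-sided enrichment between phospho and non-phospho column eluates.

    ``records`` holds one row per (protein, group) with log2 intensities in
    ``value_cols`` (default: every ``log2_rep<k>`` column). Proteins must
    have >= ``min_valid_per_group`` finite values in a group for that group
    mean to count; proteins failing in both groups are excluded (listed
    under ``"excluded"``). log2FC = mean(group A) - mean(group B) for the
    two groups in sorted order; proteins with log2FC >= ``fc_threshold`` are
    enriched in A, those with log2FC <= -``fc_threshold`` enriched in B.
    The published threshold statement is internally inconsistent, so the
    rule is applied symmetrically with both directions reported.
    """
    value_cols = value_cols or sorted(
        (c for c in records.columns if re.fullmatch(r"log2_rep\d+", c)),
        key=lambda c: int(c.rsplit("rep", 1)[1]),
    )
    if not value_cols:
        raise ValueError("no log2_rep<k> columns found")
    groups = sorted(records[group_col].unique())
    if len(groups) != 2:
        raise ValueError("enrichment_filter requires exactly 2 groups")
    ga, gb = groups

    table_rows, excluded = [], []
    for protein, grp in records.groupby("protein_id", sort=True):
        means = {}
        for g in groups:
            vals = grp.loc[grp[group_col] == g, value_cols].to_numpy(dtype=float).ravel()
            vals = vals[np.isfinite(vals)]
            means[g] = vals.mean() if len(vals) >= min_valid_per_group else np.nan
        if np.isnan(means[ga]) and np.isnan(means[gb]):
            excluded.append(protein)
            continue
        fc = means[ga] - means[gb]
        table_rows.append(
            {"protein_id": protein, f"mean_{ga}": means[ga], f"mean_{gb}": means[gb], "log2fc": fc}
        )
    table = pd.DataFrame(table_rows)
    valid = table.dropna(subset=["log2fc"]) if not table.empty else table
    enriched_a = sorted(valid.loc[valid["log2fc"] >= fc_threshold, "protein_id"]) if not table.empty else []
    enriched_b = sorted(valid.loc[valid["log2fc"] <= -fc_threshold, "protein_id"]) if not table.empty else []
    return {
        "table": table,
        f"enriched_{ga}": enriched_a,
        f"enriched_{gb}": enriched_b,
        "excluded": sorted(excluded),
    }


@dataclass
class MotifHit:
    position: int  # 1-based position of the phosphoacceptor
    residue: str
    pattern: str
    window: str  # +/- 5 residues around the acceptor


def pka_motif_scan(
    sequence: str,
    region: tuple[int, int] | None = None,
    consensus: tuple[str, ...] = DEFAULT_PKA_CONSENSUS,
) -> list[MotifHit]:
    """Scan for S/T phosphoacceptors in a PKA-like basic consensus context.

    Each pattern in ``consensus`` is a regex ending in ``[ST]`` describing
    the acceptor and its N-terminal flank. Positions are 1-based protein
    coordinates; ``region=(start, end)`` (inclusive, 1-based) restricts the
    acceptor position. A position matched by several patterns is reported
    once, with the first matching pattern.
    """
    sequence = sequence.upper()
    if not set(sequence) <= _VALID_AA:
        raise ValueError("invalid residue letters in sequence")
    start, end = region if region is not None else (1, len(sequence))
    if not (1 <= start <= end <= len(sequence)):
        raise ValueError("region outside sequence")
    hits: dict[int, MotifHit] = {}
    for pattern in consensus:
        for m in re.finditer(f"(?=({pattern}))", sequence):
            matched = m.group(1)
            pos = m.start() + len(matched)  # 1-based acceptor position
            if not (start <= pos <= end) or pos in hits:
                continue
            lo, hi = max(0, pos - 6), min(len(sequence), pos + 5)
            hits[pos] = MotifHit(
                position=pos,
                residue=sequence[pos - 1],
                pattern=pattern,
                window=sequence[lo:hi],
            )
    return [hits[p] for p in sorted(hits)]


@dataclass
class ConservationRecord:
    position: int  # reference-sequence coordinates, 1-based
    reference_residue: str
    column_residues: dict[str, str]
    conserved: int
    conservative: int  # same physicochemical class, not identical
    total: int

    @property
    def ratio(self) -> str:
        return f"{self.conserved}/{self.total}"


def conservation_ratio(alignment_path, reference_seq_id: str, position: int) -> ConservationRecord:
    """Conserved/total ratio of a site across an aligned FASTA.

    Maps the 1-based ungapped ``position`` in the reference sequence to its
    alignment column and counts sequences whose residue is identical to the
    reference residue (gaps count as non-conserved). Residues in the same
    physicochemical class (e.g. S/T) are tallied separately as
    ``conservative`` but never counted as conserved.
    """
    alignment = AlignIO.read(alignment_path, "fasta")
    reference = None
    for rec in alignment:
        if rec.id == reference_seq_id:
            reference = str(rec.seq).upper()
            break
    if reference is None:
        raise ValueError(f"reference {reference_seq_id!r} not in alignment")

    ungapped = 0
    column = None
    for col, aa in enumerate(reference):
        if aa != "-":
            ungapped += 1
            if ungapped == position:
                column = col
                break
    if column is None:
        raise ValueError("position beyond the reference sequence")
    ref_aa = reference[column]
    if ref_aa == "-":  # pragma: no cover - unreachable given the walk above
        raise ValueError("position maps to a gap in the reference")

    group = next((g for g in _CONSERVATIVE_GROUPS if ref_aa in g), {ref_aa})
    residues, conserved, conservative = {}, 0, 0
    for rec in alignment:
        aa = str(rec.seq[column]).upper()
        residues[rec.id] = aa
        if aa == ref_aa:
            conserved += 1
        elif aa in group:
            conservative += 1
    return ConservationRecord(
        position=position,
        reference_residue=ref_aa,
        column_residues=residues,
        conserved=conserved,
        conservative=conservative,
        total=len(alignment),
    )
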