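"""Family reporting: representatives, modal TSDs, and result files.

Writes four result files per run: ``all.fasta`` (every reported element,
one record per distinct individual by default), ``families.fasta`` (one
representative per surviving family), ``families.csv`` (per-family
summary), and ``mites.gff3`` (one feature per reported element, 1-based
inclusive coordinates).  Members that failed the flank-distinctness test
are putative duplication artifacts: they stay in the family record but are
excluded from the main FASTA/GFF3 and written to an audit FASTA instead.
"""

from __future__ import annotations

import csv
import os
from collections import Counter
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .family_clustering import Family
from .sequence_core import write_fasta
from .tir_search import MiteCandidate


def select_representative(family: Family) -> str:
    """The family centroid: deterministic and >= threshold identity to all."""
    if not family.member_ids:
        raise ValueError(f"family {family.family_id} is empty")
    return family.centroid_id


def most_common_tsd(
    family: Family, candidates_by_id: Dict[str, MiteCandidate]
) -> str:
    """Modal TSD string among members carrying one; "none" if no member does.

    Count ties break lexicographically (smallest string wins).
    """
    tsds = [
        candidates_by_id[mid].tsd
        for mid in family.member_ids
        if candidates_by_id[mid].tsd
    ]
    if not tsds:
        return "none"
    counts = Counter(tsds)
    top = max(counts.values())
    return min(t for t, c in counts.items() if c == top)


def _gff3_escape(value: str) -> str:
    for ch, rep in ((";", "%3B"), ("=", "%3D"), ("&", "%26"), (",", "%2C")):
        value = value.replace(ch, rep)
    return value


def reported_members(
    family: Family, include_shared: bool = False
) -> List[str]:
    """Member ids written to the main outputs, in member order."""
    if include_shared or family.distinct_ids is None:
        return list(family.member_ids)
    distinct = set(family.distinct_ids)
    return [mid for mid in family.member_ids if mid in distinct]


def write_outputs(
    families: Sequence[Family],
    candidates_by_id: Dict[str, MiteCandidate],
    output_dir: str,
    include_shared: bool = False,
) -> Dict[str, str]:
    """Write all result files for the surviving families.

    Returns a mapping of logical name ("all_fasta", "families_fasta",
    "families_csv", "gff3", and "excluded_fasta" when applicable) to path.
    Families must already carry representative_id, common_tsd and
    distinct_count.
    """
    os.makedirs(output_dir, exist_ok=True)
    paths = {
        "all_fasta": os.path.join(output_dir, "all.fasta"),
        "families_fasta": os.path.join(output_dir, "families.fasta"),
        "families_csv": os.path.join(output_dir, "families.csv"),
        "gff3": os.path.join(output_dir, "mites.gff3"),
    }
    ordered = sorted(families, key=lambda f: f.family_id)

    all_records: List[Tuple[str, str]] = []
    excluded_records: List[Tuple[str, str]] = []
    gff_rows: List[Tuple[str, int, int, str, str, str]] = []
    for fam in ordered:
        reported = set(reported_members(fam, include_shared))
        for mid in sorted(
            fam.member_ids,
            key=lambda m: (
                candidates_by_id[m].chrom,
                candidates_by_id[m].start,
                candidates_by_id[m].end,
            ),
        ):
            cand = candidates_by_id[mid]
            header = "{}|family{}|tsd={}|tir_len={}".format(
                cand.candidate_id,
                fam.family_id,
                cand.tsd or "none",
                cand.tir_len,
            )
            if mid in reported:
                all_records.append((header, cand.seq))
                gff_rows.append(
                    (
                        cand.chrom,
                        cand.start,
                        cand.end,
                        cand.candidate_id,
                        f"family{fam.family_id}",
                        cand.tsd or "none",
                    )
                )
            else:
                excluded_records.append((header, cand.seq))
    write_fasta(all_records, paths["all_fasta"])

    fam_records = []
    for fam in ordered:
        rep = fam.representative_id or select_representative(fam)
        cand = candidates_by_id[rep]
        fam_records.append(
            (
                "family{}|{}|tsd={}".format(
                    fam.family_id, rep, fam.common_tsd or "none"
                ),
                cand.seq,
            )
        )
    write_fasta(fam_records, paths["families_fasta"])

    with open(paths["families_csv"], "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["family_id", "representative_id", "members", "distinct_count",
             "common_tsd"]
        )
        for fam in ordered:
            writer.writerow(
                [
                    fam.family_id,
                    fam.representative_id or select_representative(fam),
                    len(fam.member_ids),
                    fam.distinct_count,
                    fam.common_tsd or "none",
                ]
            )

    gff_rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, start, end, cid, fam_label, tsd in gff_rows:
            attrs = "ID={};Family={};TSD={}".format(
                _gff3_escape(cid), _gff3_escape(fam_label), _gff3_escape(tsd)
            )
            fh.write(
                "\t".join(
                    [chrom, "mitefinder", "MITE", str(start + 1), str(end),
                     ".", "+", ".", attrs]
                )
                + "\n"
            )

    if excluded_records:
        paths["excluded_fasta"] = os.path.join(
            output_dir, "audit_excluded.fasta"
        )
        write_fasta(excluded_records, paths["excluded_fasta"])
    return paths
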