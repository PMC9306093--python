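"""Readers and writers for the package's plain-text interchange formats.

Genomic tables (genome build, segments, SNPs, scores) are tab-separated with
headers; the clinical cohort is CSV.  Missing values are written as ".".
All files are UTF-8.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .allele import SNP_COLUMNS
from .genome import ChromosomeInfo, GenomeBuild, Segment, SegmentProfile
from .scars import ScarScores

__all__ = [
    "read_genome",
    "write_genome",
    "read_segments",
    "write_segments",
    "read_snps",
    "write_snps",
    "write_scores",
    "read_cohort",
    "write_cohort",
]

MISSING = "."

SEGMENT_COLUMNS = ["sample", "chromosome", "start", "end", "major_cn", "minor_cn"]
SCORE_COLUMNS = ["sample", "loh", "tai", "lst", "hrd", "purity", "ploidy"]


def write_genome(genome: GenomeBuild, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (c.name, c.length, c.centromere_start, c.centromere_end)
            for c in genome
        ],
        columns=["name", "length", "centromere_start", "centromere_end"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_genome(path: str | Path) -> GenomeBuild:
    df = pd.read_csv(path, sep="\t")
    return GenomeBuild(
        tuple(
            ChromosomeInfo(
                str(r["name"]),
                int(r["length"]),
                int(r["centromere_start"]),
                int(r["centromere_end"]),
            )
            for _, r in df.iterrows()
        )
    )


def write_segments(
    profiles: Iterable[SegmentProfile], path: str | Path
) -> None:
    rows = [
        (p.sample_id, s.chromosome, s.start, s.end, s.major_cn, s.minor_cn)
        for p in profiles
        for s in p.segments
    ]
    pd.DataFrame(rows, columns=SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_segments(path: str | Path) -> list[SegmentProfile]:
    df = pd.read_csv(path, sep="\t")
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"segment table missing columns: {sorted(missing)}")
    profiles = []
    for sample, g in df.groupby("sample", sort=False):
        segs = tuple(
            Segment(
                chromosome=str(r["chromosome"]),
                start=int(r["start"]),
                end=int(r["end"]),
                major_cn=int(r["major_cn"]),
                minor_cn=int(r["minor_cn"]),
            )
            for _, r in g.iterrows()
        )
        profiles.append(SegmentProfile(sample_id=str(sample), segments=segs))
    return profiles


def write_snps(snps: pd.DataFrame, path: str | Path, sample: str = "sample") -> None:
    out = snps.loc[:, SNP_COLUMNS].copy()
    out.insert(0, "sample", sample)
    out.to_csv(path, sep="\t", index=False)


def read_snps(path: str | Path) -> dict[str, pd.DataFrame]:
    """SNP tables keyed by sample id."""
    df = pd.read_csv(path, sep="\t")
    missing = {"sample", *SNP_COLUMNS} - set(df.columns)
    if missing:
        raise ValueError(f"SNP table missing columns: {sorted(missing)}")
    return {
        str(sample): g[SNP_COLUMNS].reset_index(drop=True)
        for sample, g in df.groupby("sample", sort=False)
    }


def write_scores(scores: Mapping[str, ScarScores], path: str | Path) -> None:
    rows = [
        (
            sample,
            s.loh_score,
            s.tai_score,
            s.lst_score,
            s.hrd_score,
            s.purity_used if s.purity_used is not None else MISSING,
            s.ploidy_used if s.ploidy_used is not None else MISSING,
        )
        for sample, s in scores.items()
    ]
    pd.DataFrame(rows, columns=SCORE_COLUMNS).to_csv(path, sep="\t", index=False)


COHORT_REQUIRED = ["patient_id", "hrd_score", "idcp", "m_stage"]


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False, na_rep=MISSING)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=[MISSING])
    missing = set(COHORT_REQUIRED) - set(df.columns)
    if missing or df.empty:
        raise ValueError(
            f"cohort table invalid: missing columns {sorted(missing)}"
            if missing
            else "cohort table is empty"
        )
    return df
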