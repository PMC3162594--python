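"""Workflow orchestration: the landscape-characterization run and the
supermatrix + pruning run, with parameter logging and TSV reports."""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as oio
from .gc import landscape_report
from .model import GenomeRecord, LandscapeReport
from .regions import codon_position_sites, partition_genome
from .repeats import find_maximal_repeats, repeat_coverage, shared_repeats

logger = logging.getLogger("gclandscape")


@dataclass
class RunConfig:
    genome_paths: list[str]
    out_dir: str
    fmt: str = "genbank"
    min_len: int = 20
    shared_min_len: int = 30
    orientations: tuple[str, ...] = ("forward", "inverted")
    include_stop: bool = False
    do_repeats: bool = True
    do_shared: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not self.genome_paths:
            raise ValueError("at least one genome input is required")
        for p in self.genome_paths:
            if not Path(p).exists():
                raise FileNotFoundError(p)


def _report_frame(reports: list[LandscapeReport]) -> pd.DataFrame:
    df = pd.DataFrame([r.as_dict() for r in reports])
    num = df.select_dtypes("number").columns
    df[num] = df[num].round(3)
    return df


def _hit_frame(hits) -> pd.DataFrame:
    return pd.DataFrame([h.__dict__ for h in hits])


def run_landscape(config: RunConfig) -> pd.DataFrame:
    """One landscape report row per genome; repeat tables, BED region
    files, and (for two genomes) a shared-repeat summary alongside."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("landscape run: %s", vars(config))

    records: list[GenomeRecord] = []
    reports: list[LandscapeReport] = []
    for path in config.genome_paths:
        rec = oio.read_genome_record(path, config.fmt)
        records.append(rec)
        partition = partition_genome(rec)
        oio.write_region_table(partition, out / f"{rec.id}.regions.bed")
        has_cds = any(f.kind == "protein_coding" for f in rec.features)
        sites = (codon_position_sites(rec, config.include_stop)
                 if has_cds else None)
        rpt_pct = None
        if config.do_repeats:
            hits = find_maximal_repeats(rec, config.min_len,
                                        config.orientations)
            rpt_pct = 100.0 * repeat_coverage(hits, rec.length)
            _hit_frame(hits).to_csv(out / f"{rec.id}.repeats.tsv",
                                    sep="\t", index=False)
        reports.append(landscape_report(rec, partition, sites,
                                        repeat_pct=rpt_pct))
    df = _report_frame(reports)
    df.to_csv(out / "landscape.tsv", sep="\t", index=False)

    if config.do_shared and len(records) == 2:
        segments, summary = shared_repeats(records[0], records[1],
                                           config.shared_min_len)
        _hit_frame(segments).to_csv(out / "shared_segments.tsv",
                                    sep="\t", index=False)
        pd.DataFrame([summary.__dict__]).to_csv(
            out / "shared_summary.tsv", sep="\t", index=False)
    return df


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(stream=sys.stderr,
                        level=logging.DEBUG if verbose else logging.INFO,
                        format="%(name)s %(levelname)s %(message)s")
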