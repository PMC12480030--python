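"""Standard-format input/output: phased VCF, BED-like CNV segments, TSV tables.

VCF handling goes through pysam; genotypes are written phased (``|``
separator) with one record per defining variant. VCF positions are 1-based
and converted to the package's internal 0-based convention on read; BED
segments are native 0-based half-open with a copy-number column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam
import yaml

from .locus import AlleleDefinitionTable, GeneModel
from .simulate import CohortConfig, SimulatedHaplotypes

BED_COLUMNS = ["chrom", "start", "end", "sample_id", "svtype", "copy_number"]


def write_vcf(
    haplotypes: SimulatedHaplotypes,
    defs: AlleleDefinitionTable,
    gene: GeneModel,
    path: str,
) -> None:
    """Write phased genotypes over the defining positions to an uncompressed VCF."""
    meta = defs.variant_meta
    by_pos = {int(r.position): r for r in meta.itertuples(index=False) if r.position != "."}
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={gene.chromosome}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for sid in haplotypes.sample_ids:
        header.add_sample(sid)
    positions = defs.positions
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for j, pos in enumerate(positions):
            row = by_pos[pos]
            rec = vcf.new_record(
                contig=gene.chromosome,
                start=pos,  # pysam takes 0-based start; VCF POS = start + 1
                alleles=(row.ref, row.alt),
                id=row.rsid,
            )
            states = haplotypes.states[:, :, j]
            for i, sid in enumerate(haplotypes.sample_ids):
                rec.samples[sid]["GT"] = (int(states[i, 0]), int(states[i, 1]))
                rec.samples[sid].phased = True
            vcf.write(rec)


def read_vcf_haplotypes(path: str, defs: AlleleDefinitionTable) -> SimulatedHaplotypes:
    """Read phased genotypes back into haplotype state matrices.

    Missing genotypes become state -1. Variants at positions outside the
    definition table are ignored; absent defining positions stay reference.
    """
    positions = defs.positions
    pos_index = {p: j for j, p in enumerate(positions)}
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        states = np.zeros((len(samples), 2, len(positions)), dtype=np.int8)
        for rec in vcf:
            j = pos_index.get(rec.start)
            if j is None:
                continue
            for i, sid in enumerate(samples):
                gt = rec.samples[sid]["GT"]
                for h in (0, 1):
                    a = gt[h] if gt is not None and len(gt) == 2 else None
                    states[i, h, j] = -1 if a is None else int(a)
    return SimulatedHaplotypes(sample_ids=samples, labels=None, states=states)


def write_bed(segments: pd.DataFrame, path: str) -> None:
    """Write CNV segments as 0-based half-open BED with svtype and copy number."""
    segments[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_scenario(config: CohortConfig, path: str) -> None:
    """Serialise a cohort scenario to YAML (effect keys join with ``|``)."""
    d = {k: v for k, v in config.__dict__.items()}
    d["effects"] = {"|".join(k): float(v) for k, v in config.effects.items()}
    d["pgs_names"] = list(config.pgs_names)
    d["birth_year_range"] = list(config.birth_year_range)
    if config.pgs_corr is not None:
        d["pgs_corr"] = np.asarray(config.pgs_corr).tolist()
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def read_scenario(path: str) -> CohortConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["effects"] = {tuple(k.split("|")): v for k, v in d.get("effects", {}).items()}
    d["pgs_names"] = tuple(d.get("pgs_names", ()))
    d["birth_year_range"] = tuple(d.get("birth_year_range", (1940, 2005)))
    if d.get("pgs_corr") is not None:
        d["pgs_corr"] = np.asarray(d["pgs_corr"], dtype=float)
    return CohortConfig(**d)
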