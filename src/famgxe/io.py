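"""File formats: PLINK-style PED/MAP, phenotype/result TSVs, VCF export,
and the declarative YAML run configuration."""
from __future__ import annotations

import dataclasses
import hashlib
import json

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError
from .pedigree import FEMALE, MALE, FamilyTemplate, Individual, Pedigree
from .simulate import (
    AgeDistribution,
    CausalSnp,
    GenotypePanel,
    SimConfig,
    SnpSpec,
)

_SEX_TO_PED = {MALE: "1", FEMALE: "2"}
_PED_TO_SEX = {"1": MALE, "2": FEMALE}


# ---------------------------------------------------------------------------
# PED/MAP

def write_ped_map(pedigree: Pedigree, panel: GenotypePanel, ped_path, map_path) -> None:
    """White-space-delimited PED (fam id father mother sex pheno alleles...)
    and MAP (chrom snp cM pos).  Allele "A" is the counted (dosage) allele,
    "B" the other; dosage d writes d copies of "A"."""
    meta = panel.snp_meta
    with open(map_path, "w") as fh:
        for snp, row in meta.iterrows():
            fh.write(f"{row['chrom']}\t{snp}\t0\t{int(row['pos'])}\n")
    dos = np.rint(panel.dosages).astype(int)
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(pedigree.individuals):
            fields = [
                ind.family, ind.iid, ind.father or "0", ind.mother or "0",
                _SEX_TO_PED[ind.sex], "-9",
            ]
            for d in dos[i]:
                fields += ["A" if d >= 1 else "B", "A" if d == 2 else "B"]
            fh.write("\t".join(fields) + "\n")


def read_ped_map(ped_path, map_path) -> tuple[Pedigree, GenotypePanel]:
    """Parse PED/MAP written by :func:`write_ped_map` (PLINK dialect).

    Parent id "0" marks a founder.  Dosage is the count of allele "A".
    Round-trips bit-exactly with the writer for generated data.
    """
    snps, chroms, positions = [], [], []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(f"{map_path}:{lineno}: expected 4 fields, got {len(parts)}")
            chroms.append(parts[0])
            snps.append(parts[1])
            positions.append(int(parts[3]))
    m = len(snps)
    individuals, rows = [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            fam, iid, father, mother, sex = parts[:5]
            if sex not in _PED_TO_SEX:
                raise ParseError(f"{ped_path}:{lineno}: bad sex code {sex!r}")
            individuals.append(Individual(
                iid, None if father == "0" else father,
                None if mother == "0" else mother, _PED_TO_SEX[sex], fam,
            ))
            alleles = parts[6:]
            rows.append([
                (alleles[2 * j] == "A") + (alleles[2 * j + 1] == "A")
                for j in range(m)
            ])
    pedigree = Pedigree(individuals)
    dosages = np.asarray(rows, dtype=float)
    meta = GenotypePanel.realized_meta(
        dosages, chroms, positions, pd.Index(snps, name="snp")
    )
    return pedigree, GenotypePanel(dosages, meta, pedigree.ids)


def count_mendelian_errors(pedigree: Pedigree, panel: GenotypePanel) -> int:
    """Number of (individual, SNP) dosages unreachable from the parents."""
    dos = np.rint(panel.dosages).astype(int)
    errors = 0
    for i in range(len(pedigree)):
        f, m = pedigree.father_idx[i], pedigree.mother_idx[i]
        if f < 0:
            continue
        lo = (dos[f] == 2).astype(int) + (dos[m] == 2).astype(int)
        hi = 2 - (dos[f] == 0).astype(int) - (dos[m] == 0).astype(int)
        errors += int(((dos[i] < lo) | (dos[i] > hi)).sum())
    return errors


# ---------------------------------------------------------------------------
# phenotype and result TSVs

def write_phenotypes(phen: pd.DataFrame, path) -> None:
    phen.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_phenotypes(path) -> pd.DataFrame:
    phen = pd.read_csv(path, sep="\t", dtype={"id": str})
    return phen.set_index("id", drop=False)


def _fmt(value) -> str:
    if value is None or (isinstance(value, float) and not np.isfinite(value)):
        return "NA"
    if isinstance(value, float):
        if value != 0 and abs(value) < 1e-4:
            return f"{value:.1E}"
        return f"{value:.6g}"
    return str(value)


def write_results(results: pd.DataFrame, path, header_meta: dict | None = None) -> None:
    """Scan-result TSV; p-values below 1e-4 in scientific notation,
    '.' decimal separator, optional '# key=value' header lines."""
    with open(path, "w") as fh:
        for k, v in (header_meta or {}).items():
            fh.write(f"# {k}={v}\n")
        fh.write("\t".join(results.columns) + "\n")
        for _, row in results.iterrows():
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    df["converged"] = df["converged"].astype(str).str.lower().isin(("true", "1"))
    return df


# ---------------------------------------------------------------------------
# VCF export

def write_vcf(pedigree: Pedigree, panel: GenotypePanel, path) -> None:
    """Minimal VCF v4.2 with GT calls, one sample column per individual.
    The counted allele is ALT."""
    meta = panel.snp_meta.sort_values(["chrom", "pos"])
    dos = np.rint(panel.dosages).astype(int)
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(pedigree.ids) + "\n")
        for snp, row in meta.iterrows():
            j = panel.snp_meta.index.get_loc(snp)
            calls = "\t".join(gt[d] for d in dos[:, j])
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{snp}\tB\tA\t.\tPASS\t.\tGT\t{calls}\n")


# ---------------------------------------------------------------------------
# configuration

def config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["family_template"] = {"generations": config.family_template.generations,
                            "sibships": list(config.family_template.sibships)}
    d["null_snps"] = [dataclasses.asdict(s) for s in config.null_snps]
    d["causal_snps"] = [dataclasses.asdict(s) for s in config.causal_snps]
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "family_template" in d:
        ft = d["family_template"]
        d["family_template"] = FamilyTemplate(ft["generations"], tuple(ft["sibships"]))
    if "age_distribution" in d:
        d["age_distribution"] = AgeDistribution(**d["age_distribution"])
    d["null_snps"] = [SnpSpec(**s) for s in d.get("null_snps", [])]
    d["causal_snps"] = [CausalSnp(**s) for s in d.get("causal_snps", [])]
    return SimConfig(**d)


def save_config(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_config(path) -> SimConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def config_hash(config: SimConfig) -> str:
    blob = json.dumps(config_to_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
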