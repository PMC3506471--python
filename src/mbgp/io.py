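"""Plain-text readers and writers: VCF, dosage matrix, pedigree and
phenotype CSV, relationship matrices."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from mbgp.data import GenotypeMatrix, Pedigree, RelationshipMatrix


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write unphased GT records (0/0, 0/1, 1/1, ./. for missing)."""
    codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted(set(int(c) for c in genotypes.chrom)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.animal_ids) + "\n")
        X = genotypes.dosages
        for j, snp in enumerate(genotypes.snp_ids):
            gts = "\t".join("./." if np.isnan(X[i, j]) else codes[X[i, j]]
                            for i in range(genotypes.n_animals))
            fh.write(f"{int(genotypes.chrom[j])}\t{int(genotypes.pos[j])}\t"
                     f"{snp}\tA\tB\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a (plain-text) VCF with GT fields into a dosage matrix."""
    animal_ids: list[str] = []
    snp_ids, chrom, pos, rows = [], [], [], []
    gt_map = {"0/0": 0.0, "0/1": 1.0, "1/0": 1.0, "1/1": 2.0, "./.": np.nan,
              "0|0": 0.0, "0|1": 1.0, "1|0": 1.0, "1|1": 2.0, ".|.": np.nan}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                animal_ids = fields[9:]
                continue
            chrom.append(int(fields[0]))
            pos.append(int(fields[1]))
            snp_ids.append(fields[2])
            gt_idx = fields[8].split(":").index("GT")
            rows.append([gt_map[s.split(":")[gt_idx]] for s in fields[9:]])
    return GenotypeMatrix(animal_ids=animal_ids, snp_ids=snp_ids,
                          chrom=np.array(chrom), pos=np.array(pos),
                          dosages=np.array(rows, dtype=float).T)


def write_dosage_matrix(genotypes: GenotypeMatrix, path) -> None:
    """Whitespace-delimited: header of SNP ids, one row per animal,
    missing written as NA. A side file ``<path>.map`` carries the map."""
    with open(path, "w") as fh:
        fh.write("animal_id " + " ".join(genotypes.snp_ids) + "\n")
        for i, animal in enumerate(genotypes.animal_ids):
            vals = " ".join("NA" if np.isnan(v) else f"{v:g}"
                            for v in genotypes.dosages[i])
            fh.write(f"{animal} {vals}\n")
    pd.DataFrame({"snp_id": genotypes.snp_ids, "chrom": genotypes.chrom,
                  "pos": genotypes.pos}).to_csv(f"{path}.map", index=False)


def read_dosage_matrix(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+", na_values="NA")
    snp_ids = df.columns[1:].tolist()
    map_path = Path(f"{path}.map")
    if map_path.exists():
        mp = pd.read_csv(map_path)
        chrom = mp["chrom"].to_numpy()
        pos = mp["pos"].to_numpy()
    else:
        chrom = np.ones(len(snp_ids), dtype=int)
        pos = np.arange(1, len(snp_ids) + 1)
    return GenotypeMatrix(animal_ids=df.iloc[:, 0].astype(str).tolist(),
                          snp_ids=snp_ids, chrom=chrom, pos=pos,
                          dosages=df.iloc[:, 1:].to_numpy(dtype=float))


def write_pedigree(pedigree: Pedigree, path) -> None:
    pedigree.table.to_csv(path, index=False)


def read_pedigree(path) -> Pedigree:
    table = pd.read_csv(path, dtype={"animal_id": str, "sire_id": str,
                                     "dam_id": str, "sire_family": str},
                        keep_default_na=False)
    table["founder_breed"] = table["founder_breed"].astype(str)
    return Pedigree(table=table)


def write_relationship_matrix(matrix: RelationshipMatrix, path,
                              sparse: bool = False) -> None:
    """Dense CSV with id header, or three-column (id1, id2, value) text."""
    if sparse:
        with open(path, "w") as fh:
            fh.write("id1,id2,value\n")
            for i, a in enumerate(matrix.ids):
                for j in range(i, len(matrix.ids)):
                    fh.write(f"{a},{matrix.ids[j]},{matrix.values[i, j]:.10g}\n")
    else:
        pd.DataFrame(matrix.values, index=matrix.ids,
                     columns=matrix.ids).to_csv(path)


def read_relationship_matrix(path, kind: str) -> RelationshipMatrix:
    df = pd.read_csv(path, index_col=0)
    return RelationshipMatrix(ids=[str(i) for i in df.index],
                              values=df.to_numpy(dtype=float), kind=kind)
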