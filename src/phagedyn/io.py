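"""TSV/FASTA readers and writers for the pipeline's intermediate tables.

All tables are plain tab-separated text with a header row; matrices are wide
(species/taxon rows x monthly sample columns). Missing months are encoded as
absent columns plus a `months.tsv` sidecar carrying the full monthly axis and
a missing flag.
"""

from __future__ import annotations

import os

import pandas as pd

from .synthetic import SpeciesCountTable, SyntheticDataset


def write_matrix(df: pd.DataFrame, path: str, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_fasta(sequences: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, seq in sequences.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    cur = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                cur = line[1:].split()[0]
                if cur in seqs:
                    raise ValueError(f"duplicate FASTA id {cur!r}")
                seqs[cur] = []
            else:
                if cur is None:
                    raise ValueError("FASTA data before first header")
                seqs[cur].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


def write_count_table(table: SpeciesCountTable, outdir: str) -> None:
    tag = table.fraction_label
    write_matrix(table.counts, os.path.join(outdir, f"counts_{tag}.tsv"), "species")
    write_matrix(table.base_coverage, os.path.join(outdir, f"coverage_{tag}.tsv"), "species")
    write_matrix(table.mean_depth, os.path.join(outdir, f"depth_{tag}.tsv"), "species")
    table.gene_length.to_frame().to_csv(
        os.path.join(outdir, "gene_lengths.tsv"), sep="\t", index_label="species"
    )
    table.library_size.to_frame().to_csv(
        os.path.join(outdir, f"library_sizes_{tag}.tsv"), sep="\t", index_label="sample"
    )


def read_count_table(outdir: str, fraction_label: str) -> SpeciesCountTable:
    tag = fraction_label
    return SpeciesCountTable(
        counts=read_matrix(os.path.join(outdir, f"counts_{tag}.tsv")),
        gene_length=read_matrix(os.path.join(outdir, "gene_lengths.tsv"))["gene_length"],
        library_size=read_matrix(os.path.join(outdir, f"library_sizes_{tag}.tsv"))[
            "library_size"
        ],
        base_coverage=read_matrix(os.path.join(outdir, f"coverage_{tag}.tsv")),
        mean_depth=read_matrix(os.path.join(outdir, f"depth_{tag}.tsv")),
        fraction_label=fraction_label,
    )


def write_dataset(ds: SyntheticDataset, outdir: str) -> None:
    """Write the full synthetic dataset as the standard pipeline inputs."""
    os.makedirs(outdir, exist_ok=True)
    write_count_table(ds.counts_viral, outdir)
    write_count_table(ds.counts_cellular, outdir)
    write_matrix(ds.host_abundance, os.path.join(outdir, "host_abundance.tsv"), "taxon")
    write_matrix(ds.env, os.path.join(outdir, "env.tsv"), "covariate")
    ds.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t")
    pd.DataFrame(
        {"month": [str(m) for m in ds.months], "missing": ds.missing.to_numpy().astype(int)}
    ).to_csv(os.path.join(outdir, "months.tsv"), sep="\t", index=False)
    write_fasta(ds.sequences, os.path.join(outdir, "markers.fasta"))


def read_dataset(outdir: str) -> SyntheticDataset:
    months_df = pd.read_csv(os.path.join(outdir, "months.tsv"), sep="\t", dtype={"month": str})
    months = pd.PeriodIndex(months_df["month"], freq="M")
    missing = pd.Series(
        months_df["missing"].astype(bool).to_numpy(), index=months_df["month"].tolist()
    )
    return SyntheticDataset(
        counts_viral=read_count_table(outdir, "viral"),
        counts_cellular=read_count_table(outdir, "cellular"),
        host_abundance=read_matrix(os.path.join(outdir, "host_abundance.tsv")),
        env=read_matrix(os.path.join(outdir, "env.tsv")),
        truth=pd.read_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index_col="species"),
        months=months,
        missing=missing,
        sequences=read_fasta(os.path.join(outdir, "markers.fasta")),
        seed=-1,
    )
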