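"""Readers and writers for parameter bundles, sequences and tables.

The parameter bundle is a JSON file with scalars plus relative references
to TSV matrices (rows A, C, G, T in that fixed order; columns ordered
upstream to downstream), a spacer-penalty table and a dinucleotide-term
table.  Saving then loading reproduces every numeric field at full
precision, and the JSON is written with canonical key order so repeated
round trips are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .model import BASES, DinucleotideTerm, EnergyModel, PromoterSequence, find_rbs
from .sortseq import SortSeqLibrary

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """Parameter bundle has an unknown or incompatible schema version."""


def _matrix_to_tsv(mat: np.ndarray, path: Path) -> None:
    df = pd.DataFrame(mat, index=list(BASES),
                      columns=[f"pos_{j}" for j in range(mat.shape[1])])
    df.to_csv(path, sep="\t", index_label="base", float_format="%.17g")


def _matrix_from_tsv(path: Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", index_col="base",
                     float_precision="round_trip")
    if list(df.index) != list(BASES):
        raise ValueError(f"{path}: rows must be A,C,G,T in order, "
                         f"got {list(df.index)}")
    expected = [f"pos_{j}" for j in range(df.shape[1])]
    if list(df.columns) != expected:
        missing = set(expected) - set(df.columns)
        raise ValueError(f"{path}: missing/misnamed position column(s): "
                         f"{sorted(missing) or list(df.columns)}")
    return df.to_numpy(dtype=float)


def save_bundle(model: EnergyModel, directory: str | Path,
                name: str = "model") -> Path:
    """Write a parameter bundle; returns the path of the JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    up_tsv = f"{name}_upstream.tsv"
    down_tsv = f"{name}_downstream.tsv"
    _matrix_to_tsv(model.upstream_block, directory / up_tsv)
    _matrix_to_tsv(model.downstream_block, directory / down_tsv)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "upstream_block": up_tsv,
        "downstream_block": down_tsv,
        "spacer_penalties": {str(k): model.spacer_penalties[k]
                             for k in sorted(model.spacer_penalties)},
        "dinucleotide_terms": [
            {"pos_i": t.pos_i, "base_i": t.base_i, "pos_j": t.pos_j,
             "base_j": t.base_j, "delta_e": t.delta_e}
            for t in model.dinucleotide_terms],
        "mu": model.mu,
        "clearance_rate": model.clearance_rate,
        "rbs_occlusion_cutoff": model.rbs_occlusion_cutoff,
    }
    path = directory / f"{name}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def load_bundle(path: str | Path) -> EnergyModel:
    """Load a parameter bundle from its JSON manifest."""
    path = Path(path)
    try:
        manifest = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"{path}: malformed bundle JSON at line "
                         f"{e.lineno}: {e.msg}") from e
    version = manifest.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaError(f"{path}: schema version {version!r}, "
                          f"expected {SCHEMA_VERSION}")
    base = path.parent
    return EnergyModel(
        upstream_block=_matrix_from_tsv(base / manifest["upstream_block"]),
        downstream_block=_matrix_from_tsv(base / manifest["downstream_block"]),
        spacer_penalties={int(k): float(v) for k, v
                          in manifest["spacer_penalties"].items()},
        dinucleotide_terms=[DinucleotideTerm(**t)
                            for t in manifest["dinucleotide_terms"]],
        mu=float(manifest["mu"]),
        clearance_rate=float(manifest["clearance_rate"]),
        rbs_occlusion_cutoff=int(manifest["rbs_occlusion_cutoff"]),
    )


def kcal_per_mol_to_kbt(value: float) -> float:
    """Convert kcal/mol to the package's k_B*T energy unit."""
    from .model import KBT_KCAL_PER_MOL
    return value / KBT_KCAL_PER_MOL


# ---------------------------------------------------------------------------
# sequences


def read_sequences(fasta_path: str | Path,
                   rbs_sidecar: str | Path | None = None,
                   auto_rbs: bool = False) -> list[PromoterSequence]:
    """Read a multi-record FASTA, with optional RBS annotations.

    RBS positions come from a sidecar TSV (columns ``identifier``,
    ``rbs_start``) or, with ``auto_rbs``, from the first Shine-Dalgarno
    motif occurrence in each record.
    """
    sidecar = {}
    if rbs_sidecar is not None:
        df = pd.read_csv(rbs_sidecar, sep="\t")
        sidecar = dict(zip(df["identifier"], df["rbs_start"].astype(int)))
    out = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        bases = str(rec.seq).upper()
        rbs = sidecar.get(rec.id)
        if rbs is None and auto_rbs:
            rbs = find_rbs(bases)
        out.append(PromoterSequence(identifier=rec.id, bases=bases,
                                    rbs_start=rbs))
    return out


def write_fasta(seqs: list[PromoterSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.identifier}\n{s.bases}\n")


# ---------------------------------------------------------------------------
# libraries, gates, tracks


def read_library(path: str | Path,
                 gates_yaml: str | Path | None = None) -> SortSeqLibrary:
    """Read a count table TSV (columns sequence, count_bin_0..B-1)."""
    df = pd.read_csv(path, sep="\t")
    medians = None
    if gates_yaml is not None:
        meta = yaml.safe_load(Path(gates_yaml).read_text())
        medians = np.asarray(meta["bin_medians"], dtype=float)
    return SortSeqLibrary.from_frame(df, bin_medians=medians)


def write_library(lib: SortSeqLibrary, path: str | Path) -> None:
    lib.to_frame().to_csv(path, sep="\t", index=False)


def write_gates(path: str | Path, gates: np.ndarray,
                bin_medians: np.ndarray | None = None) -> None:
    meta = {"gates_log10_pon": [float(g) for g in np.asarray(gates)]}
    if bin_medians is not None:
        meta["bin_medians"] = [float(m) for m in np.asarray(bin_medians)]
    Path(path).write_text(yaml.safe_dump(meta, sort_keys=True))


def write_track(track, path: str | Path, chrom: str = "genome") -> None:
    """BEDGRAPH-style TSV of a genome free-energy track."""
    df = pd.DataFrame({
        "chrom": chrom,
        "start": track.positions,
        "end": track.positions + 1,
        "free_energy": track.free_energy,
    })
    df.to_csv(path, sep="\t", index=False)


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Feature table for region partitioning.

    Accepts a TSV with columns ``type``, ``start``, ``end`` (0-based
    half-open) or a GFF3 file (coordinates converted from 1-based
    inclusive).
    """
    path = Path(path)
    first = ""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first = line
                break
    if first.startswith("##gff") or first.count("\t") == 8:
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                rows.append({"type": f[2], "start": int(f[3]) - 1,
                             "end": int(f[4])})
        return pd.DataFrame(rows)
    return pd.read_csv(path, sep="\t")[["type", "start", "end"]]
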