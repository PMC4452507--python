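"""TSV readers/writers and dataset assembly with the interactor filter.

All artifacts are UTF-8 TSV with ``#`` comment lines. IDs are opaque
strings; nothing is validated against external databases. Floats are
written with Python's shortest round-trip repr so write-then-read is exact
and reruns are bit-for-bit reproducible.

Dataset assembly applies the interactor rule: in *strict* mode an
association is kept only when both its drug and its disease have at least
one interacting gene present in the network; in *relaxed* mode one side
suffices. The drug/disease universes are the entities appearing in the kept
associations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import BipartiteInteractions
from .mf import LabeledPairSet, MatrixFactorization
from .network import FeatureSpace, GeneNetwork

logger = logging.getLogger(__name__)


def _fmt(x: float) -> str:
    return repr(float(x))


def _rows(path, n_fields: int, header: bool = False):
    """Yield (line_number, fields) from a TSV, skipping comments/blanks."""
    first_data = True
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if header and first_data:
                first_data = False
                continue
            first_data = False
            fields = line.split("\t")
            if len(fields) != n_fields:
                raise ValueError(
                    f"{path}:{ln}: expected {n_fields} tab-separated fields, "
                    f"got {len(fields)}"
                )
            yield ln, [f.strip() for f in fields]


# -- edge lists and pair lists ---------------------------------------------


def read_network(path, header: bool = False) -> GeneNetwork:
    """Gene-gene edge list: two gene IDs per line."""
    return GeneNetwork.from_edges(fields for _, fields in _rows(path, 2, header))


def write_network(network: GeneNetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# gene_a\tgene_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in network.graph.edges):
            fh.write(f"{a}\t{b}\n")


def read_bipartite(path, header: bool = False) -> BipartiteInteractions:
    """Entity-gene pair list (drug-gene or disease-gene)."""
    pairs = []
    seen = set()
    for ln, (e, g) in _rows(path, 2, header):
        if (e, g) in seen:
            logger.warning("%s:%d: duplicate interaction (%s, %s) ignored", path, ln, e, g)
            continue
        seen.add((e, g))
        pairs.append((e, g))
    return BipartiteInteractions.from_pairs(pairs)


def write_bipartite(inter: BipartiteInteractions, path, kind: str = "entity") -> None:
    row_pos = {r: i for i, r in enumerate(inter.row_ids)}
    col_pos = {c: i for i, c in enumerate(inter.col_ids)}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {kind}\tgene\n")
        for r, c in sorted(inter.pairs, key=lambda p: (row_pos[p[0]], col_pos[p[1]])):
            fh.write(f"{r}\t{c}\n")


def read_associations(path, header: bool = False) -> list[tuple[str, str]]:
    """Known positive drug-disease associations; dedup with a warning."""
    out, seen = [], set()
    for ln, (d, s) in _rows(path, 2, header):
        if (d, s) in seen:
            logger.warning("%s:%d: duplicate association (%s, %s) ignored", path, ln, d, s)
            continue
        seen.add((d, s))
        out.append((d, s))
    return out


def write_associations(assocs, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# drug\tdisease\n")
        for d, s in assocs:
            fh.write(f"{d}\t{s}\n")


# -- numeric artifacts ------------------------------------------------------


def write_feature_space(space: FeatureSpace, path) -> None:
    """ID-indexed TSV: first column the entity ID, then k feature columns."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(f"f{j}" for j in range(space.k)) + "\n")
        for i, eid in enumerate(space.ids):
            fh.write(eid + "\t" + "\t".join(_fmt(x) for x in space.X[i]) + "\n")


def read_feature_space(path) -> FeatureSpace:
    ids, rows = [], []
    with open(path, encoding="utf-8") as fh:
        n_cols = None
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if n_cols is None:  # header
                n_cols = len(fields)
                continue
            if len(fields) != n_cols:
                raise ValueError(f"{path}:{ln}: ragged row")
            ids.append(fields[0])
            rows.append([float(x) for x in fields[1:]])
    return FeatureSpace(ids=ids, X=np.array(rows))


def write_relation_matrix(gene_ids, C: np.ndarray, path) -> None:
    """Header row of gene IDs, then the numeric body."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(gene_ids) + "\n")
        for row in C:
            fh.write("\t".join(_fmt(x) for x in row) + "\n")


def read_relation_matrix(path) -> tuple[list[str], np.ndarray]:
    with open(path, encoding="utf-8") as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip() and not l.startswith("#")]
    gene_ids = lines[0].split("\t")
    C = np.array([[float(x) for x in l.split("\t")] for l in lines[1:]])
    return gene_ids, C


def save_model(model: MatrixFactorization, outdir) -> None:
    """A/B factor TSVs plus a key=value metadata file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    drug_ids = getattr(model, "drug_ids_", [str(i) for i in range(model.A_.shape[0])])
    disease_ids = getattr(model, "disease_ids_", [str(i) for i in range(model.B_.shape[0])])
    write_feature_space(FeatureSpace(ids=drug_ids, X=model.A_), outdir / "A.tsv")
    write_feature_space(FeatureSpace(ids=disease_ids, X=model.B_), outdir / "B.tsv")
    meta = {
        "k": model.k,
        "lambda_reg": _fmt(model.lambda_reg),
        "eta": _fmt(model.eta),
        "n_epochs": getattr(model, "n_epochs_", 0),
        "final_loss": _fmt(model.loss_trace_[-1]) if hasattr(model, "loss_trace_") else "",
    }
    with open(outdir / "meta.txt", "w", encoding="utf-8") as fh:
        for key, val in meta.items():
            fh.write(f"{key}={val}\n")


def load_model(outdir) -> MatrixFactorization:
    outdir = Path(outdir)
    A_space = read_feature_space(outdir / "A.tsv")
    B_space = read_feature_space(outdir / "B.tsv")
    meta = read_config(outdir / "meta.txt")
    model = MatrixFactorization(
        k=int(meta["k"]),
        lambda_reg=float(meta["lambda_reg"]),
        eta=float(meta["eta"]),
    )
    model.warm_start(A_space.X, B_space.X)
    model.drug_ids_ = A_space.ids
    model.disease_ids_ = B_space.ids
    return model


def write_predictions(drug_ids, disease_ids, scores, path) -> None:
    """Three-column TSV: drug ID, disease ID, association score."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# drug\tdisease\tscore\n")
        for d, s, x in zip(drug_ids, disease_ids, scores):
            fh.write(f"{d}\t{s}\t{_fmt(x)}\n")


def read_config(path) -> dict[str, str]:
    """Flat key=value file; '#' comments and blank lines ignored."""
    out = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected key=value")
            key, _, val = line.partition("=")
            out[key.strip()] = val.strip()
    return out


# -- dataset assembly -------------------------------------------------------


@dataclass(frozen=True)
class Dataset:
    """Filtered inputs ready for feature extraction and training."""

    network: GeneNetwork
    drug_genes: BipartiteInteractions
    disease_genes: BipartiteInteractions
    positives: list[tuple[str, str]]
    provenance: dict = field(default_factory=dict, repr=False)

    def positive_pairs(self) -> LabeledPairSet:
        """Positives as index pairs into the drug/disease ID orders."""
        dpos = {d: i for i, d in enumerate(self.drug_genes.row_ids)}
        spos = {s: i for i, s in enumerate(self.disease_genes.row_ids)}
        return LabeledPairSet.from_samples(
            (dpos[d], spos[s], 1) for d, s in self.positives
        )


def _interactor_map(inter: BipartiteInteractions, network: GeneNetwork):
    """entity -> set of interacting genes that are network nodes."""
    out: dict[str, set] = {}
    for e, g in inter.pairs:
        if g in network:
            out.setdefault(e, set()).add(g)
    return out


def assemble_dataset(
    network: GeneNetwork,
    drug_genes: BipartiteInteractions,
    disease_genes: BipartiteInteractions,
    associations,
    strict: bool = True,
    provenance: dict | None = None,
) -> Dataset:
    """Apply the interactor filter and restrict to the surviving entities."""
    associations = list(associations)
    if not associations:
        raise ValueError("no associations")
    drug_map = _interactor_map(drug_genes, network)
    disease_map = _interactor_map(disease_genes, network)
    if strict:
        kept = [(d, s) for d, s in associations if d in drug_map and s in disease_map]
    else:
        kept = [(d, s) for d, s in associations if d in drug_map or s in disease_map]
    if not kept:
        raise ValueError("no associations survive the interactor filter")
    drugs = list(dict.fromkeys(d for d, _ in kept))
    diseases = list(dict.fromkeys(s for _, s in kept))
    genes = sorted(
        {g for d in drugs for g in drug_map.get(d, ())}
        | {g for s in diseases for g in disease_map.get(s, ())}
    )
    dg = BipartiteInteractions(
        row_ids=drugs, col_ids=genes,
        pairs=frozenset((d, g) for d in drugs for g in drug_map.get(d, ())),
    )
    sg = BipartiteInteractions(
        row_ids=diseases, col_ids=genes,
        pairs=frozenset((s, g) for s in diseases for g in disease_map.get(s, ())),
    )
    prov = dict(provenance or {})
    prov.update(
        n_associations_in=len(associations),
        n_associations_kept=len(kept),
        n_associations_dropped=len(associations) - len(kept),
        n_drugs=len(drugs),
        n_diseases=len(diseases),
        n_genes=len(genes),
        strict=strict,
    )
    return Dataset(
        network=network, drug_genes=dg, disease_genes=sg,
        positives=kept, provenance=prov,
    )


def load_dataset(
    network_path, drug_genes_path, disease_genes_path, associations_path,
    strict: bool = True, header: bool = False,
) -> Dataset:
    """Read the four TSV inputs and assemble the filtered dataset."""
    network = read_network(network_path, header=header)
    drug_genes = read_bipartite(drug_genes_path, header=header)
    disease_genes = read_bipartite(disease_genes_path, header=header)
    associations = read_associations(associations_path, header=header)
    prov = {
        "network_path": str(network_path),
        "drug_genes_path": str(drug_genes_path),
        "disease_genes_path": str(disease_genes_path),
        "associations_path": str(associations_path),
    }
    return assemble_dataset(
        network, drug_genes, disease_genes, associations,
        strict=strict, provenance=prov,
    )
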