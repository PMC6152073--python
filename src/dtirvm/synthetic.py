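"""Seeded generators for synthetic PSSMs, interaction networks and features.

Every generator is a pure function of its parameters and seed, so fixtures
are reproduced at test time instead of being stored.  The defaults mirror
the shape of the enzyme benchmark commonly used for drug-target interaction
studies: 445 drugs, 664 protein targets, 2,926 known interactions, and
integer PSSM scores in the magnitude range PSI-BLAST log-odds occupy.

Synthetic PSSMs are i.i.d. uniform integer matrices — they reproduce the
shape and value range of real profiles, not the positional correlation
structure of homologous protein families.  Class structure for end-to-end
classifier tests is injected directly at the feature level as two Gaussian
clouds with a controllable mean separation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np

from .features import FeatureMatrix
from .pipeline import InteractionNetwork
from .pssm_io import AA_ORDER, PSSM


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset."""

    seed: int = 0
    pssm_length_range: Tuple[int, int] = (50, 400)
    score_range: Tuple[int, int] = (-10, 10)
    n_drugs: int = 445
    n_targets: int = 664
    n_positive: int = 2926
    class_separation: float = 6.0

    def __post_init__(self) -> None:
        if self.pssm_length_range[0] > self.pssm_length_range[1]:
            raise ValueError("pssm_length_range min > max")
        if self.score_range[0] > self.score_range[1]:
            raise ValueError("score_range min > max")
        if min(self.n_drugs, self.n_targets) < 1:
            raise ValueError("n_drugs and n_targets must be positive")
        if not (1 <= self.n_positive <= self.n_drugs * self.n_targets):
            raise ValueError(
                f"n_positive must be in [1, {self.n_drugs * self.n_targets}]")
        if self.class_separation < 0:
            raise ValueError("class_separation must be >= 0")


def gen_pssm(length: int, seed: int,
             spec: Optional[SyntheticSpec] = None,
             protein_id: str = "synthetic") -> PSSM:
    """Random raw PSSM: i.i.d. uniform integer scores over the spec range."""
    if length < 1:
        raise ValueError("length must be >= 1")
    lo, hi = (spec or SyntheticSpec()).score_range
    rng = np.random.default_rng(seed)
    scores = rng.integers(lo, hi + 1, size=(length, 20)).astype(float)
    sequence = "".join(rng.choice(list(AA_ORDER), size=length))
    return PSSM(protein_id=protein_id, scores=scores,
                sequence=sequence, normalization="raw")


def gen_network(spec: SyntheticSpec) -> InteractionNetwork:
    """Random bipartite network with ids d0001.../t0001... and uniform edges."""
    dw = max(4, len(str(spec.n_drugs)))
    tw = max(4, len(str(spec.n_targets)))
    drug_ids = [f"d{i + 1:0{dw}d}" for i in range(spec.n_drugs)]
    target_ids = [f"t{j + 1:0{tw}d}" for j in range(spec.n_targets)]
    rng = np.random.default_rng(spec.seed)
    flat = rng.choice(spec.n_drugs * spec.n_targets,
                      size=spec.n_positive, replace=False)
    edges = {(drug_ids[f // spec.n_targets], target_ids[f % spec.n_targets])
             for f in flat}
    return InteractionNetwork(drug_ids=drug_ids, target_ids=target_ids,
                              positive_edges=edges)


def gen_two_class_features(n_per_class: int, dim: int, separation: float,
                           seed: int) -> Tuple[FeatureMatrix, np.ndarray]:
    """Two unit-variance Gaussian clouds with Euclidean mean distance ``separation``.

    Class 0 is centered at -s/2 * 1 and class 1 at +s/2 * 1 with
    s = separation / sqrt(dim), so the distance between the class means is
    exactly ``separation`` regardless of dimension.
    """
    if n_per_class < 1 or dim < 1:
        raise ValueError("n_per_class and dim must be >= 1")
    rng = np.random.default_rng(seed)
    shift = separation / np.sqrt(dim) / 2.0
    X0 = rng.standard_normal((n_per_class, dim)) - shift
    X1 = rng.standard_normal((n_per_class, dim)) + shift
    X = np.vstack([X0, X1])
    labels = np.concatenate([np.zeros(n_per_class, dtype=int),
                             np.ones(n_per_class, dtype=int)])
    ids = [f"s{i + 1:05d}" for i in range(2 * n_per_class)]
    return FeatureMatrix(ids=ids, X=X), labels


def write_psiblast_ascii(p: PSSM, path: Union[str, Path]) -> None:
    """Emit a PSSM in the PSI-BLAST ``-out_ascii_pssm`` ASCII dialect.

    Written for synthetic fixtures: the log-odds block carries the matrix,
    the percentage block is filled with zeros, and the two per-row
    statistics are placeholders.
    """
    if p.normalization != "raw":
        raise ValueError("only raw integer PSSMs can be written in ASCII form")
    seq = p.sequence or "A" * p.length
    letters = " ".join(AA_ORDER)
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "           " + letters + "   " + letters,
    ]
    for i, row in enumerate(p.scores):
        scores = " ".join(f"{int(v):3d}" for v in row)
        pcts = " ".join(f"{0:3d}" for _ in range(20))
        lines.append(f"{i + 1:5d} {seq[i]}  {scores}  {pcts}  0.00 0.00")
    lines += ["", "                      K         Lambda", ""]
    Path(path).write_text("\n".join(lines))


def write_synthetic_dataset(spec: SyntheticSpec, out_dir: Union[str, Path]) -> dict:
    """Write a complete on-disk synthetic dataset (PSSMs, FASTA, pairs, manifest).

    Returns the manifest dictionary, which also lands in ``manifest.json``.
    Child seeds are derived deterministically from ``spec.seed``.
    """
    out_dir = Path(out_dir)
    pssm_dir = out_dir / "pssm"
    pssm_dir.mkdir(parents=True, exist_ok=True)

    net = gen_network(spec)
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.pssm_length_range
    fasta_path = out_dir / "targets.fasta"
    pssm_files = []
    with fasta_path.open("w") as fasta:
        for j, tid in enumerate(net.target_ids):
            length = int(rng.integers(lo, hi + 1))
            child_seed = int(rng.integers(0, 2 ** 31 - 1))
            p = gen_pssm(length, seed=child_seed, spec=spec, protein_id=tid)
            path = pssm_dir / f"{tid}.pssm"
            write_psiblast_ascii(p, path)
            pssm_files.append(path.name)
            fasta.write(f">{tid}\n{p.sequence}\n")

    pairs_path = out_dir / "positive_pairs.tsv"
    net.to_pairs_tsv(pairs_path)

    manifest = {
        "seed": spec.seed,
        "n_drugs": spec.n_drugs,
        "n_targets": spec.n_targets,
        "n_positive": spec.n_positive,
        "pssm_length_range": list(spec.pssm_length_range),
        "score_range": list(spec.score_range),
        "class_separation": spec.class_separation,
        "files": {
            "fasta": fasta_path.name,
            "pairs": pairs_path.name,
            "pssm_dir": "pssm",
            "pssm_files": pssm_files,
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
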