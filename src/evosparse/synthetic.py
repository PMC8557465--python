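"""Synthetic alignments with planted clade-diagnostic signal.

The generator emulates the signal structure the method assumes: most
alignment positions evolve independently of the focal clade, while a small
set of diagnostic positions carries a "clade state" preferentially in
clade members. Signal strength is controlled by two probabilities:
``fidelity`` (a member carries the clade state) and ``leakage`` (a
non-member carries it). Genes partition the positions contiguously; a few
genes concentrate all the diagnostic positions.

Defaults mirror a modest phylogenomic screen: 100 sequences, 2,000
nucleotide positions in 20 equal genes, a 30-taxon focal clade, two
diagnostic genes with 10 diagnostic positions each at fidelity 0.95 and
leakage 0.05. Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .msa_io import Alignment, GroupMap, alphabet_states, write_alignment


class SimulationError(ValueError):
    pass


@dataclass
class SimulationTruth:
    """Ground truth of one simulated data set."""

    clade_members: list[str]
    diagnostic_positions: dict[int, tuple[str, str]]  # pos -> (clade, background)
    diagnostic_genes: list[str]
    fidelity: float
    leakage: float
    seed: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        d["diagnostic_positions"] = {
            str(k): list(v) for k, v in self.diagnostic_positions.items()
        }
        return json.dumps(d, indent=1)


@dataclass
class SimulatedData:
    alignment: Alignment
    positives: set[str] = field(default_factory=set)
    groups: GroupMap | None = None
    truth: SimulationTruth | None = None

    def write(self, out_dir) -> None:
        """FASTA + RAxML partition file + class TSV + truth JSON."""
        import os

        os.makedirs(out_dir, exist_ok=True)
        write_alignment(self.alignment, os.path.join(out_dir, "alignment.fasta"))
        dtype = "DNA" if self.alignment.alphabet == "nucleotide" else "WAG"
        with open(os.path.join(out_dir, "partitions.txt"), "w") as fh:
            for name, poss in zip(self.groups.names, self.groups.positions):
                fh.write(f"{dtype}, {name} = {min(poss)}-{max(poss)}\n")
        with open(os.path.join(out_dir, "classes.tsv"), "w") as fh:
            for t in self.alignment.taxa:
                fh.write(f"{t}\t{'+1' if t in self.positives else '-1'}\n")
        with open(os.path.join(out_dir, "truth.json"), "w") as fh:
            fh.write(self.truth.to_json())


def simulate(
    S: int = 100,
    p: int = 2000,
    G: int = 20,
    n_diag_genes: int = 2,
    n_diag_per_gene: int = 10,
    clade_size: int = 30,
    fidelity: float = 0.95,
    leakage: float = 0.05,
    alphabet: str = "nucleotide",
    seed: int = 0,
    composition: np.ndarray | None = None,
) -> SimulatedData:
    """Simulate an alignment with planted clade-diagnostic genes.

    Non-diagnostic positions are drawn i.i.d. from ``composition``
    (uniform over the alphabet by default). Each diagnostic position has a
    clade state and a distinct background state: clade members carry the
    clade state with probability ``fidelity``, non-members with
    probability ``leakage``; otherwise the background state. Diagnostic
    positions are spread over ``n_diag_genes`` genes chosen at random.
    """
    if not (2 <= clade_size <= S - 2):
        raise SimulationError("clade_size must be in [2, S-2]")
    if not (0.0 <= leakage < fidelity <= 1.0):
        raise SimulationError("need 0 <= leakage < fidelity <= 1")
    if G < 1 or G > p:
        raise SimulationError("need 1 <= G <= p")
    if n_diag_genes > G:
        raise SimulationError("more diagnostic genes than genes")
    states = alphabet_states(alphabet)
    rng = np.random.default_rng(seed)
    if composition is None:
        composition = np.full(len(states), 1.0 / len(states))
    composition = np.asarray(composition, dtype=np.float64)
    if composition.size != len(states) or not np.isclose(composition.sum(), 1.0):
        raise SimulationError("composition must be a distribution over the alphabet")

    # contiguous, near-equal genes
    bounds = np.linspace(0, p, G + 1).astype(int)
    gene_names = [f"gene{g + 1:03d}" for g in range(G)]
    positions = [
        tuple(range(bounds[g] + 1, bounds[g + 1] + 1)) for g in range(G)
    ]
    if any(len(q) == 0 for q in positions):
        raise SimulationError("more genes than positions")
    if any(len(q) < n_diag_per_gene for q in positions):
        raise SimulationError("n_diag_per_gene exceeds gene length")
    groups = GroupMap(names=gene_names, positions=positions)

    width = int(np.ceil(np.log10(max(S, 2))))
    taxa = [f"t{i + 1:0{width}d}" for i in range(S)]
    members = sorted(rng.choice(S, size=clade_size, replace=False))
    member_mask = np.zeros(S, dtype=bool)
    member_mask[members] = True
    positives = {taxa[i] for i in members}

    diag_gene_idx = sorted(rng.choice(G, size=n_diag_genes, replace=False))
    diag_positions: dict[int, tuple[str, str]] = {}
    C = np.empty((S, p), dtype="<U1")
    base = rng.choice(list(states), size=(S, p), p=composition)
    C[:, :] = base
    for gi in diag_gene_idx:
        chosen = rng.choice(
            len(positions[gi]), size=n_diag_per_gene, replace=False
        )
        for k in sorted(chosen):
            pos = positions[gi][int(k)]
            clade_state, background = rng.choice(list(states), size=2, replace=False)
            carries = np.where(
                member_mask,
                rng.random(S) < fidelity,
                rng.random(S) < leakage,
            )
            C[:, pos - 1] = np.where(carries, clade_state, background)
            diag_positions[pos] = (str(clade_state), str(background))

    aln = Alignment(
        taxa=taxa, rows=["".join(row) for row in C], alphabet=alphabet
    )
    truth = SimulationTruth(
        clade_members=[taxa[i] for i in members],
        diagnostic_positions=diag_positions,
        diagnostic_genes=[gene_names[i] for i in diag_gene_idx],
        fidelity=fidelity,
        leakage=leakage,
        seed=seed,
    )
    return SimulatedData(alignment=aln, positives=positives, groups=groups, truth=truth)
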