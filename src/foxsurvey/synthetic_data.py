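"""Simulated multi-subfamily protein families with known trees and labels.

Emulates the structure the ortholog survey assumes: a family of
transcription-factor-like proteins split into subfamilies, each protein
carrying a conserved ~100-residue domain that evolves slowly between
divergent flanking regions, plus unrelated decoy proteins in every
proteome.  Because the generating tree, domain coordinates and subfamily
labels are known exactly, every pipeline stage — search, domain excision,
alignment, tree building, reverse best hit and the final ortholog call —
can be scored against ground truth.

Substitutions follow a 20-state equal-exchangeability Poisson model:
events arrive at rate ``20·r/19`` per site per unit branch length and
replace the residue with a uniform draw over all 20 amino acids, so the
expected number of actual changes per site per unit branch is ``r`` and
the expected identity of two sequences separated by path length ``t`` is
``1/20 + (19/20)·exp(−20·r·t/19)`` (see :func:`expected_identity`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skbio import TreeNode

from .phylo import PhyloTree
from .seq_io import SequenceRecord, write_fasta

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# Robinson-Robinson style background composition (rounded, renormalized).
_BACKGROUND = np.array(
    [
        0.079, 0.019, 0.054, 0.063, 0.040, 0.074, 0.022, 0.051, 0.058, 0.091,
        0.022, 0.045, 0.052, 0.043, 0.051, 0.068, 0.059, 0.066, 0.014, 0.032,
    ]
)
_BACKGROUND = _BACKGROUND / _BACKGROUND.sum()

_SUBFAMILY_NAMES = ["FoxJ1", "FoxJ2", "FoxN3", "FoxD2", "FoxK1", "FoxA1", "FoxO3", "FoxP2"]


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the family simulator (defaults emulate a Fox-like family)."""

    n_subfamilies: int = 5
    taxa_per_subfamily: int = 8
    domain_length: int = 100
    flank_length: int = 150
    domain_rate: float = 1.0   # substitutions/site per unit branch length
    flank_rate: float = 2.5
    subfamily_depth: float = 0.15  # mean backbone branch length
    within_subfamily_depth: float = 0.05
    indel_rate: float = 0.0    # events/site on flanks
    n_decoys: int = 3
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("n_subfamilies", "taxa_per_subfamily", "domain_length", "flank_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("domain_rate", "flank_rate", "subfamily_depth",
                     "within_subfamily_depth", "indel_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.flank_rate < self.domain_rate:
            raise ValueError("flank_rate must be >= domain_rate (flanks diverge faster)")
        if self.n_decoys < 0:
            raise ValueError("n_decoys must be >= 0")

    def subfamily_names(self) -> list[str]:
        names = list(_SUBFAMILY_NAMES)
        while len(names) < self.n_subfamilies:
            names.append(f"FoxX{len(names)}")
        return names[: self.n_subfamilies]


@dataclass
class SimulatedFamily:
    """A simulated family plus its ground truth."""

    params: SimulationParams
    true_tree: PhyloTree
    proteins: list[SequenceRecord]
    labels: dict[str, str]
    decoys: dict[str, list[SequenceRecord]]  # organism -> decoy proteins
    domain_regions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def protein(self, organism: str) -> SequenceRecord:
        for p in self.proteins:
            if p.id == organism:
                return p
        raise KeyError(organism)

    def domain_of(self, organism: str) -> SequenceRecord:
        p = self.protein(organism)
        start, end = self.domain_regions[organism]
        return SequenceRecord(
            id=p.id,
            residues=p.residues[start - 1 : end],
            region=(start, end),
            parent_id=p.id,
        )


def _random_join_tree(names: list[str], depth: float, rng: np.random.Generator) -> TreeNode:
    """Random binary topology by sequential joins; exponential branch lengths."""
    lineages = [TreeNode(name=n) for n in names]
    for node in lineages:
        node.length = float(rng.exponential(depth)) if depth > 0 else 0.0
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        b = lineages.pop(j)
        a = lineages.pop(i)
        parent = TreeNode(children=[a, b])
        parent.length = float(rng.exponential(depth)) if depth > 0 else 0.0
        lineages.append(parent)
    root = lineages[0]
    root.length = None
    return root


def _evolve(seq: np.ndarray, rate: float, t: float, rng: np.random.Generator) -> np.ndarray:
    """One branch of the 20-state uniform-exchange Poisson process."""
    if rate == 0.0 or t == 0.0:
        return seq.copy()
    mu = 20.0 * rate / 19.0
    hit = rng.poisson(mu * t, size=seq.size) > 0
    out = seq.copy()
    out[hit] = rng.integers(0, 20, size=int(hit.sum()))
    return out


def expected_identity(rate: float, path_length: float) -> float:
    """Closed-form expected pairwise identity at total path length ``t``."""
    return 1.0 / 20.0 + (19.0 / 20.0) * np.exp(-20.0 * rate * path_length / 19.0)


def _decode(seq: np.ndarray) -> str:
    return "".join(_AMINO_ACIDS[seq])


def simulate_family(params: SimulationParams) -> SimulatedFamily:
    """Simulate a labeled multi-subfamily family (reproducible per seed).

    A backbone tree over subfamilies is sampled first, then an
    independent within-subfamily tree per subfamily; the root protein
    (flank + domain + flank, drawn from background composition) is
    evolved along the composite tree with the domain and flanks at their
    own rates.  Optional indels (geometric lengths, p = 0.5) are applied
    to flanks only, so recorded domain coordinates stay exact.
    """
    rng = np.random.default_rng(params.seed)
    subfams = params.subfamily_names()
    backbone = _random_join_tree(subfams, params.subfamily_depth, rng)
    # graft within-subfamily trees onto the backbone leaves (a one-subfamily
    # backbone is itself a tip, which tips() does not yield)
    backbone_tips = [backbone] if backbone.is_tip() else list(backbone.tips())
    for tip in backbone_tips:
        sub_names = [f"{tip.name}_t{k}" for k in range(params.taxa_per_subfamily)]
        if params.taxa_per_subfamily == 1:
            sub = TreeNode(name=sub_names[0])
            sub.length = tip.length
        else:
            sub = _random_join_tree(sub_names, params.within_subfamily_depth, rng)
            sub.length = tip.length
        if tip.is_root():
            backbone = sub
        else:
            parent = tip.parent
            parent.remove(tip)
            parent.append(sub)

    L_dom, L_fl = params.domain_length, params.flank_length
    root_seq = rng.choice(20, size=L_fl + L_dom + L_fl, p=_BACKGROUND)
    dom_slice = slice(L_fl, L_fl + L_dom)

    leaf_seqs: dict[str, np.ndarray] = {}

    def _walk(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            t = child.length or 0.0
            out = seq.copy()
            out[:L_fl] = _evolve(seq[:L_fl], params.flank_rate, t, rng)
            out[dom_slice] = _evolve(seq[dom_slice], params.domain_rate, t, rng)
            out[L_fl + L_dom:] = _evolve(seq[L_fl + L_dom:], params.flank_rate, t, rng)
            if child.is_tip():
                leaf_seqs[child.name] = out
            else:
                _walk(child, out)

    if backbone.is_tip():
        leaf_seqs[backbone.name] = root_seq
    else:
        _walk(backbone, root_seq)

    proteins: list[SequenceRecord] = []
    labels: dict[str, str] = {}
    decoys: dict[str, list[SequenceRecord]] = {}
    domain_regions: dict[str, tuple[int, int]] = {}
    for name in sorted(leaf_seqs):
        subfam = name.rsplit("_t", 1)[0]
        seq = leaf_seqs[name]
        left = _decode(seq[:L_fl])
        dom = _decode(seq[dom_slice])
        right = _decode(seq[L_fl + L_dom:])
        if params.indel_rate > 0:
            left = _apply_indels(left, params.indel_rate, rng)
            right = _apply_indels(right, params.indel_rate, rng)
        residues = left + dom + right
        rec = SequenceRecord(id=name, residues=residues, description=f"simulated {subfam}")
        domain_regions[name] = (len(left) + 1, len(left) + L_dom)
        proteins.append(rec)
        labels[name] = subfam
        decoys[name] = [
            SequenceRecord(
                id=f"{name}_decoy{k}",
                residues=_decode(rng.choice(20, size=L_fl + L_dom + L_fl, p=_BACKGROUND)),
                description="decoy (background composition)",
            )
            for k in range(params.n_decoys)
        ]

    tree = PhyloTree(root=backbone if not backbone.is_tip() else TreeNode(children=[backbone]))
    return SimulatedFamily(
        params=params,
        true_tree=tree,
        proteins=proteins,
        labels=labels,
        decoys=decoys,
        domain_regions=domain_regions,
    )


def _apply_indels(flank: str, rate: float, rng: np.random.Generator) -> str:
    """Geometric-length (p=0.5) insertions/deletions on a flank."""
    n_events = rng.poisson(rate * len(flank))
    s = list(flank)
    for _ in range(n_events):
        if not s:
            break
        pos = int(rng.integers(0, len(s)))
        length = int(rng.geometric(0.5))
        if rng.random() < 0.5:
            del s[pos : pos + length]
        else:
            ins = _decode(rng.choice(20, size=length, p=_BACKGROUND))
            s[pos:pos] = list(ins)
    return "".join(s)


@dataclass
class SurveyFixture:
    """Paths of a written on-disk survey fixture plus its ground truth."""

    family: SimulatedFamily
    proteome_paths: dict[str, Path]
    panel_domain_path: Path
    panel_full_path: Path
    panel_labels_path: Path
    truth_path: Path
    reference_organisms: dict[str, str]  # subfamily -> designated organism


def make_survey_fixture(params: SimulationParams, out_dir: str | Path) -> SurveyFixture:
    """Write one proteome FASTA per organism, a labeled reference panel and
    a truth table.

    The panel is built from one designated reference taxon per subfamily
    (taxon 0, the simulator's "mouse-like" genome): its exact domain and
    full-length sequences, labeled with the subfamily name.  The truth TSV
    has one row per simulated organism mapping it to its subfamily.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    family = simulate_family(params)

    proteome_dir = out_dir / "proteomes"
    proteome_dir.mkdir(exist_ok=True)
    proteome_paths: dict[str, Path] = {}
    for protein in family.proteins:
        path = proteome_dir / f"{protein.id}.fasta"
        if path.exists():
            raise FileExistsError(f"output collision: {path}")
        write_fasta([protein] + family.decoys[protein.id], path)
        proteome_paths[protein.id] = path

    reference_organisms = {
        subfam: f"{subfam}_t0" for subfam in params.subfamily_names()
    }
    panel_domains = []
    panel_fulls = []
    label_lines = ["# panel id\tsubfamily"]
    for subfam, organism in reference_organisms.items():
        dom = family.domain_of(organism)
        ref_id = f"ref_{subfam}"
        panel_domains.append(
            SequenceRecord(id=ref_id, residues=dom.residues, description=f"{subfam} reference domain")
        )
        panel_fulls.append(
            SequenceRecord(
                id=ref_id,
                residues=family.protein(organism).residues,
                description=f"{subfam} reference full-length",
            )
        )
        label_lines.append(f"{ref_id}\t{subfam}")

    panel_domain_path = out_dir / "panel_domains.fasta"
    panel_full_path = out_dir / "panel_full.fasta"
    panel_labels_path = out_dir / "panel_labels.tsv"
    truth_path = out_dir / "truth.tsv"
    write_fasta(panel_domains, panel_domain_path)
    write_fasta(panel_fulls, panel_full_path)
    panel_labels_path.write_text("\n".join(label_lines) + "\n")
    with truth_path.open("w") as fh:
        fh.write("organism\tsubfamily\n")
        for organism in sorted(family.labels):
            fh.write(f"{organism}\t{family.labels[organism]}\n")

    return SurveyFixture(
        family=family,
        proteome_paths=proteome_paths,
        panel_domain_path=panel_domain_path,
        panel_full_path=panel_full_path,
        panel_labels_path=panel_labels_path,
        truth_path=truth_path,
        reference_organisms=reference_organisms,
    )
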