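"""Reverse best hit, ortholog decision rules and the survey report.

A candidate is assigned to a Fox subfamily by three lines of evidence:

1. *reverse best hit* — its excised domain is re-searched against the
   labeled reference panel and inherits the label of the best-scoring
   entry (with a bit-score margin over the best entry of any other
   subfamily; sub-bit margins are called ambiguous);
2. *domain phylogeny* — whether the candidate groups with the
   target-subfamily references in the domain NJ tree, and at what
   bootstrap support;
3. *full-length phylogeny* — the same query on the full-length tree,
   when a full-length record exists.

The call is *definite* when the domain phylogeny groups the candidate
with the target at bootstrap support above the threshold (default 95);
otherwise *candidate* when at least one method supports the target
(evidence from a single method is flagged as weak; two or more methods
is the stricter "identifiable" rule used for problematic groups such as
the fungi); *not detected* when no method supports it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .pairwise import DEFAULT_SCHEME, ScoringScheme, smith_waterman
from .seq_io import ReferencePanel, SequenceRecord

#: Bootstrap-support threshold for a definite ortholog call.
DEFAULT_SUPPORT_THRESHOLD = 95.0

#: Reverse-best-hit margins below this many bits are called ambiguous.
RBH_TIE_BITS = 1.0

AMBIGUOUS = "ambiguous"

METHOD_RBH = "reverse_hit"
METHOD_DOMAIN = "domain_phylogeny"
METHOD_FULL = "fulllength_phylogeny"


@dataclass
class EvidenceRecord:
    """Per-candidate evidence triple feeding the ortholog call."""

    candidate_id: str
    organism: str
    group: str = ""
    best_evalue: float | None = None
    rbh_call: str | None = None
    rbh_margin: float | None = None
    domain_grouped: bool = False
    domain_support: float | None = None
    fulllength_grouped: bool | None = None
    fulllength_support: float | None = None
    paralog_index: int = 1

    def __post_init__(self) -> None:
        for sup in (self.domain_support, self.fulllength_support):
            if sup is not None and not (0.0 <= sup <= 100.0):
                raise ValueError(f"{self.candidate_id}: support {sup} outside [0, 100]")
        if self.rbh_margin is not None and self.rbh_margin < 0:
            raise ValueError(f"{self.candidate_id}: negative reverse-hit margin")


@dataclass(frozen=True)
class OrthologCall:
    """Category plus the methods that supported it."""

    category: str  # "definite" | "candidate" | "not_detected"
    methods_supporting: frozenset[str]
    rationale: str


def reverse_best_hit(
    domain: SequenceRecord,
    panel: ReferencePanel,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> tuple[str | None, float]:
    """Assign ``domain`` the subfamily of its best-scoring panel entry.

    Returns ``(label, margin)`` where ``margin`` is the bit-score gap to
    the best entry of any *other* subfamily (infinite for a one-subfamily
    panel).  Margins below :data:`RBH_TIE_BITS` yield the label
    ``"ambiguous"``; no positive-scoring hit yields ``(None, 0.0)``.
    """
    best_by_subfamily: dict[str, float] = {}
    for entry in panel.entries:
        aln = smith_waterman(domain, entry.record, scheme)
        if aln.is_empty:
            continue
        bits = aln.bit_score
        if bits > best_by_subfamily.get(entry.subfamily, float("-inf")):
            best_by_subfamily[entry.subfamily] = bits
    if not best_by_subfamily:
        return None, 0.0
    ranked = sorted(best_by_subfamily.items(), key=lambda kv: (-kv[1], kv[0]))
    top_label, top_bits = ranked[0]
    margin = top_bits - ranked[1][1] if len(ranked) > 1 else float("inf")
    if margin < RBH_TIE_BITS:
        return AMBIGUOUS, margin
    return top_label, margin


def methods_supporting(ev: EvidenceRecord, target: str = "FoxJ1") -> frozenset[str]:
    """Which of the three methods support assignment to ``target``."""
    methods = set()
    if ev.rbh_call is not None and ev.rbh_call.lower() == target.lower():
        methods.add(METHOD_RBH)
    if ev.domain_grouped:
        methods.add(METHOD_DOMAIN)
    if ev.fulllength_grouped:
        methods.add(METHOD_FULL)
    return frozenset(methods)


def call_ortholog(
    ev: EvidenceRecord,
    support_threshold: float = DEFAULT_SUPPORT_THRESHOLD,
    target: str = "FoxJ1",
) -> OrthologCall:
    """Apply the decision rules to one evidence record.

    definite — domain phylogeny groups the candidate with the target at
    bootstrap support strictly above ``support_threshold``;
    candidate — at least one method supports the target (a single
    supporting method is annotated as weak evidence; two or more satisfy
    the stricter "identifiable" rule);
    not_detected — no method supports it.
    """
    methods = methods_supporting(ev, target=target)
    if (
        ev.domain_grouped
        and ev.domain_support is not None
        and ev.domain_support > support_threshold
    ):
        return OrthologCall(
            category="definite",
            methods_supporting=methods,
            rationale=(
                f"domain phylogeny groups with {target} at bootstrap "
                f"{ev.domain_support:g} > {support_threshold:g}"
            ),
        )
    if methods:
        weak = " (weak: single method)" if len(methods) == 1 else ""
        return OrthologCall(
            category="candidate",
            methods_supporting=methods,
            rationale=f"supported by {len(methods)} of 3 methods{weak}",
        )
    return OrthologCall(
        category="not_detected", methods_supporting=methods, rationale="no supporting method"
    )


def species_supported_by(
    evidence: list[EvidenceRecord],
    min_methods: int = 2,
    group: str | None = None,
    target: str = "FoxJ1",
) -> set[str]:
    """Organisms with at least ``min_methods`` supporting methods.

    An organism qualifies if any of its proteins (paralogs) does.
    """
    out = set()
    for ev in evidence:
        if group is not None and ev.group != group:
            continue
        if len(methods_supporting(ev, target=target)) >= min_methods:
            out.add(ev.organism)
    return out


def species_supported_by_methods(
    evidence: list[EvidenceRecord],
    required: set[str],
    group: str | None = None,
    target: str = "FoxJ1",
) -> set[str]:
    """Organisms for which all ``required`` methods support the target."""
    out = set()
    for ev in evidence:
        if group is not None and ev.group != group:
            continue
        if required <= methods_supporting(ev, target=target):
            out.add(ev.organism)
    return out


def survey_report(
    evidence: list[EvidenceRecord],
    support_threshold: float = DEFAULT_SUPPORT_THRESHOLD,
    target: str = "FoxJ1",
) -> tuple[pd.DataFrame, dict]:
    """Tabulate evidence and calls, one row per protein (paralogs separate).

    Returns the per-protein table and a summary with the identified /
    definite / candidate tallies and per-group breakdowns.  Identification
    follows the permissive ">= 1 method" listing rule; the stricter
    ">= 2 methods" tally is reported alongside.
    """
    seen = set()
    rows = []
    for ev in evidence:
        if ev.candidate_id in seen:
            raise ValueError(f"duplicate candidate id {ev.candidate_id!r}")
        seen.add(ev.candidate_id)
        call = call_ortholog(ev, support_threshold=support_threshold, target=target)
        n_methods = len(call.methods_supporting)
        rows.append(
            {
                "candidate_id": ev.candidate_id,
                "organism": ev.organism,
                "group": ev.group,
                "paralog_index": ev.paralog_index,
                "best_evalue": ev.best_evalue,
                "rbh_call": ev.rbh_call,
                "rbh_margin": ev.rbh_margin,
                "domain_grouped": ev.domain_grouped,
                "domain_support": ev.domain_support,
                "fulllength_grouped": ev.fulllength_grouped,
                "fulllength_support": ev.fulllength_support,
                "n_methods": n_methods,
                "category": call.category,
                "rationale": call.rationale,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "candidate_id", "organism", "group", "paralog_index", "best_evalue",
            "rbh_call", "rbh_margin", "domain_grouped", "domain_support",
            "fulllength_grouped", "fulllength_support", "n_methods",
            "category", "rationale",
        ],
    )
    if len(table):
        identified = table[table["n_methods"] >= 1]
        by_group = {
            g: {
                "n_proteins": int(len(sub)),
                "n_definite": int((sub["category"] == "definite").sum()),
            }
            for g, sub in identified.groupby("group")
        }
        summary = {
            "n_proteins_identified": int(len(identified)),
            "n_definite": int((table["category"] == "definite").sum()),
            "n_candidate": int((table["category"] == "candidate").sum()),
            "n_not_detected": int((table["category"] == "not_detected").sum()),
            "n_identified_two_methods": int((table["n_methods"] >= 2).sum()),
            "by_group": by_group,
        }
    else:
        summary = {
            "n_proteins_identified": 0,
            "n_definite": 0,
            "n_candidate": 0,
            "n_not_detected": 0,
            "n_identified_two_methods": 0,
            "by_group": {},
        }
    return table, summary


# ---------------------------------------------------------------------------
# packaged survey-evidence table

#: Qualitative phylogeny cells mapping to "grouped with the target".
_GROUPED_VALUES = {"foxj1"}

PACKAGED_EVIDENCE = Path(__file__).parent / "data" / "foxj1_survey_evidence.tsv"


def load_survey_evidence(path: str | Path = PACKAGED_EVIDENCE) -> list[EvidenceRecord]:
    """Load an evidence TSV (the packaged FoxJ1 survey table by default).

    Phylogeny cells are mapped to flags as follows: ``FoxJ1``/``Foxj1`` →
    grouped with the target; ``Sister to …`` / ``Unresolved`` → not
    grouped; an empty cell → analysis absent (``None``).  Bootstrap cells
    are percentages or empty.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    evidence = []
    for _, row in df.iterrows():
        phylo_dom = row["phylo_domain"].strip()
        phylo_full = row["phylo_full"].strip()
        evidence.append(
            EvidenceRecord(
                candidate_id=row["candidate_id"],
                organism=row["organism"],
                group=row["group"],
                best_evalue=float(row["evalue"]) if row["evalue"] else None,
                rbh_call=row["reverse_blast"] or None,
                domain_grouped=phylo_dom.lower() in _GROUPED_VALUES,
                domain_support=float(row["bootstrap_domain"]) if row["bootstrap_domain"] else None,
                fulllength_grouped=(
                    None if not phylo_full else phylo_full.lower() in _GROUPED_VALUES
                ),
                fulllength_support=float(row["bootstrap_full"]) if row["bootstrap_full"] else None,
                paralog_index=int(row["paralog_index"]) if row.get("paralog_index") else 1,
            )
        )
    return evidence


def write_evidence_tsv(evidence: list[EvidenceRecord], path: str | Path) -> None:
    """Write evidence records in the same TSV schema the loader reads."""
    with Path(path).open("w") as fh:
        fh.write(
            "candidate_id\torganism\tgroup\tparalog_index\tevalue\treverse_blast\t"
            "phylo_domain\tbootstrap_domain\tphylo_full\tbootstrap_full\n"
        )
        for ev in evidence:
            def fmt_flag(flag):
                if flag is None:
                    return ""
                return "FoxJ1" if flag else "Unresolved"

            fh.write(
                "\t".join(
                    [
                        ev.candidate_id,
                        ev.organism,
                        ev.group,
                        str(ev.paralog_index),
                        "" if ev.best_evalue is None else f"{ev.best_evalue:g}",
                        ev.rbh_call or "",
                        "FoxJ1" if ev.domain_grouped else "Unresolved",
                        "" if ev.domain_support is None else f"{ev.domain_support:g}",
                        fmt_flag(ev.fulllength_grouped),
                        "" if ev.fulllength_support is None else f"{ev.fulllength_support:g}",
                    ]
                )
                + "\n"
            )
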