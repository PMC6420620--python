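"""Multi-evidence derivation of the minimal plasma-membrane signature.

The surface signature of the target population is assembled by staged
set algebra over independent evidence layers:

1. label-free whole-extract presence lists -> proteins exclusive to the
   target population, filtered to the plasma membrane;
2. enriched membrane-fraction presence lists -> additional
   target-exclusive membrane proteins not seen in whole extracts;
3. the consolidated protein core (union of 1 and 2), cross-checked by
   the isobaric-label quantification (``Zq``);
4. the transcriptome core: genes differentially expressed in the target
   population in both comparisons (concordant direction), filtered to
   the plasma membrane;
5. the verified subgroup (core intersect RNA core) and the combined
   signature (union), with per-member provenance.

Plus the cross-omics concordance metrics (shared identifications and
their percentages, with the report's rounding conventions: one decimal
for within-proteome fractions, nearest integer for cross-identification
and confirmation percentages).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import pandas as pd

from .synthdata import PLASMA_MEMBRANE

log = logging.getLogger(__name__)


def pct_nearest_int(num: int, den: int) -> int:
    """Percentage rounded to the nearest integer (report convention)."""
    return int(round(100.0 * num / den))


def pct_one_decimal(num: int, den: int) -> float:
    """Percentage rounded to one decimal (report convention)."""
    return round(100.0 * num / den, 1)


def venn_partition(sets: dict[str, set]) -> dict[frozenset, set]:
    """Disjoint membership regions of named sets.

    For three sets this is the classic 7-region Venn partition; keys are
    frozensets of the names whose sets contain the region's elements.
    Regions are pairwise disjoint and union to the union of all inputs.
    """
    names = list(sets)
    regions: dict[frozenset, set] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(set(sets[n]) for n in combo))
            outside = set().union(*(set(sets[n]) for n in names if n not in combo)) if len(combo) < len(names) else set()
            regions[frozenset(combo)] = inside - outside
    return regions


def exclusive_to(sets: dict[str, set], name: str) -> set:
    """Members detected in ``name`` and in none of the other sets."""
    return venn_partition(sets)[frozenset({name})]


def deg_specific(
    deg_a: pd.DataFrame,
    deg_b: pd.DataFrame,
    alpha: float,
    direction: str = "both",
) -> set:
    """Genes significant and direction-concordant in BOTH comparisons.

    ``direction`` restricts to genes up (positive log2 FC in both),
    down, or either as long as the signs agree.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if direction not in ("up", "down", "both"):
        raise ValueError(f"direction must be up/down/both, got {direction!r}")
    if deg_a.empty or deg_b.empty:
        return set()
    a = deg_a.set_index("gene")
    b = deg_b.set_index("gene")
    common = a.index.intersection(b.index)
    a, b = a.loc[common], b.loc[common]
    sig = (a["padj"] < alpha) & (b["padj"] < alpha)
    if direction == "up":
        sel = sig & (a["log2fc"] > 0) & (b["log2fc"] > 0)
    elif direction == "down":
        sel = sig & (a["log2fc"] < 0) & (b["log2fc"] < 0)
    else:
        sel = sig & (a["log2fc"] * b["log2fc"] > 0)
    return set(common[sel])


def membrane_filter(s: set, compartments, label: str = PLASMA_MEMBRANE) -> set:
    """Members whose compartment equals ``label``.

    Members absent from the compartment map are excluded and counted in
    the log.
    """
    unknown = {m for m in s if m not in compartments}
    if unknown:
        log.info("membrane filter: %d members with unknown compartment excluded", len(unknown))
    return {m for m in s - unknown if compartments[m] == label}


def consolidate_core(
    whole_extract_exclusive_membrane: set,
    membrane_fraction_additional: set,
) -> tuple[set, dict[str, str]]:
    """Union the two membrane evidence sets with per-member provenance.

    The second set is expected to be disjoint from the first (proteins
    not previously detected in whole extracts); an overlap is logged and
    deduplicated with provenance ``"both"``.
    """
    overlap = whole_extract_exclusive_membrane & membrane_fraction_additional
    if overlap:
        log.warning("consolidate_core: %d proteins present in both evidence sets", len(overlap))
    provenance = {m: "whole_extract" for m in whole_extract_exclusive_membrane}
    for m in membrane_fraction_additional:
        provenance[m] = "both" if m in overlap else "membrane_fraction"
    return whole_extract_exclusive_membrane | membrane_fraction_additional, provenance


def itraq_confirm(
    core: set,
    protein_table: pd.DataFrame,
    rule: str = "positive",
    threshold: float | None = None,
) -> tuple[set, int | None]:
    """Subset of the core confirmed by the isobaric-label quantification.

    ``rule="positive"`` (default): quantified with ``Zq > 0``.
    ``rule="abs_threshold"``: quantified with ``|Zq| >= threshold``.
    Returns the confirmed subset and its percentage of the core (nearest
    integer), or ``None`` for an empty core.
    """
    if rule not in ("positive", "abs_threshold"):
        raise ValueError(f"unknown confirmation rule {rule!r}")
    if rule == "abs_threshold" and threshold is None:
        raise ValueError("rule 'abs_threshold' needs a threshold")
    if not core:
        return set(), None
    zq = protein_table.dropna(subset=["Zq"]).set_index("protein")["Zq"]
    quantified = core & set(zq.index)
    if rule == "positive":
        confirmed = {m for m in quantified if zq[m] > 0}
    else:
        confirmed = {m for m in quantified if abs(zq[m]) >= threshold}
    log.info(
        "isobaric confirmation (%s): %d/%d core members quantified, %d confirmed",
        rule,
        len(quantified),
        len(core),
        len(confirmed),
    )
    return confirmed, pct_nearest_int(len(confirmed), len(core))


def rna_membrane_core(deg_specific_up: set, compartments) -> set:
    """Membrane filter applied to the up-direction two-comparison DEG set."""
    return membrane_filter(deg_specific_up, compartments)


@dataclass
class SignatureReport:
    """Staged signature derivation output with per-member provenance."""

    core: set
    rna_core: set
    verified: set
    combined: set
    overlap_pct: int
    provenance: pd.DataFrame
    counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # inclusion-exclusion must hold exactly for the reported counts
        assert len(self.combined) == len(self.core) + len(self.rna_core) - len(self.verified)


def build_signature(
    core: set,
    rna_core: set,
    core_provenance: dict[str, str] | None = None,
    confirmed: set | None = None,
) -> SignatureReport:
    """Verified subgroup (intersection) and combined signature (union).

    The overlap percentage is ``100 * |core & rna_core| / |rna_core|``
    rounded to the nearest integer.
    """
    if not core or not rna_core:
        raise ValueError("both the protein core and the RNA membrane core must be non-empty")
    verified = core & rna_core
    combined = core | rna_core
    provenance = pd.DataFrame(
        {
            "member": sorted(combined),
        }
    ).set_index("member")
    provenance["in_protein_core"] = [m in core for m in provenance.index]
    provenance["in_rna_membrane_core"] = [m in rna_core for m in provenance.index]
    provenance["verified_both"] = [m in verified for m in provenance.index]
    src = core_provenance or {}
    provenance["whole_extract_exclusive"] = [src.get(m) == "whole_extract" for m in provenance.index]
    provenance["membrane_fraction_only"] = [src.get(m) == "membrane_fraction" for m in provenance.index]
    provenance["itraq_confirmed"] = [m in (confirmed or set()) for m in provenance.index]
    counts = {
        "n_core": len(core),
        "n_rna_core": len(rna_core),
        "n_verified": len(verified),
        "n_combined": len(combined),
    }
    return SignatureReport(
        core=set(core),
        rna_core=set(rna_core),
        verified=verified,
        combined=combined,
        overlap_pct=pct_nearest_int(len(verified), len(rna_core)),
        provenance=provenance,
        counts=counts,
    )


def cross_identification(proteome: set, transcriptome: set) -> dict:
    """Concordance of the two omics layers' identifications.

    Returns the shared count, the share of the proteome also identified
    by transcriptomics (one decimal), the cross-identification
    percentage (nearest integer) and the share of the transcriptome also
    seen in the proteome (one decimal).  Percentages are ``None`` when a
    layer is empty.
    """
    shared = proteome & transcriptome
    out = {
        "n_proteome": len(proteome),
        "n_transcriptome": len(transcriptome),
        "n_shared": len(shared),
        "proteome_in_transcriptome_pct": None,
        "cross_identification_pct": None,
        "transcriptome_in_proteome_pct": None,
    }
    if proteome:
        out["proteome_in_transcriptome_pct"] = pct_one_decimal(len(shared), len(proteome))
        out["cross_identification_pct"] = pct_nearest_int(len(shared), len(proteome))
    if transcriptome:
        out["transcriptome_in_proteome_pct"] = pct_one_decimal(len(shared), len(transcriptome))
    return out


def evaluate_against_truth(signature_set: set, truth_entities: pd.DataFrame) -> dict:
    """Sensitivity and precision of a derived set vs. the planted markers."""
    planted = set(truth_entities.index[truth_entities["is_planted_surface"]])
    tp = len(signature_set & planted)
    return {
        "n_planted": len(planted),
        "n_signature": len(signature_set),
        "true_positives": tp,
        "sensitivity": tp / len(planted) if planted else float("nan"),
        "precision": tp / len(signature_set) if signature_set else float("nan"),
    }
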