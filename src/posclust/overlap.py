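"""Directional overlap between two gene lists with hypergeometric significance.

Used for comparisons such as "genes upregulated during conidiation" versus
"genes downregulated in the deletion strain": the overlap is reported as a
count, as a percentage of each list, and with an upper-tail hypergeometric
p-value against a stated gene universe (by default the genome gene count).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom

from .io import GeneList, ValidationError

__all__ = ["OverlapResult", "directional_overlap", "reciprocal_overlap"]


@dataclass
class OverlapResult:
    """Overlap of lists A and B within a universe of ``n_universe`` genes."""

    n_a: int
    n_b: int
    n_universe: int
    n_overlap: int
    pct_of_a: float
    pct_of_b: float
    hypergeometric_p: float
    shared_ids: tuple[str, ...]

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["shared_ids"] = list(self.shared_ids)
        return d


def directional_overlap(list_a: GeneList, list_b: GeneList, universe: int) -> OverlapResult:
    """Intersection of two deduplicated gene lists.

    ``hypergeometric_p`` is the upper-tail probability of drawing at least
    ``n_overlap`` of B's genes when ``n_a`` genes are sampled without
    replacement from a universe containing ``n_b`` marked genes; a zero
    overlap therefore yields p = P(X >= 0) = 1.
    """
    a, b = set(list_a.ids), set(list_b.ids)
    union = a | b
    if universe < len(union):
        raise ValidationError(
            f"universe ({universe}) smaller than |A ∪ B| ({len(union)})"
        )
    shared = tuple(sorted(a & b))
    k = len(shared)
    p = float(hypergeom.sf(k - 1, universe, len(b), len(a)))
    return OverlapResult(
        n_a=len(a),
        n_b=len(b),
        n_universe=universe,
        n_overlap=k,
        pct_of_a=100.0 * k / len(a) if a else 0.0,
        pct_of_b=100.0 * k / len(b) if b else 0.0,
        hypergeometric_p=min(p, 1.0),
        shared_ids=shared,
    )


def reciprocal_overlap(
    up_a: GeneList, down_a: GeneList, up_b: GeneList, down_b: GeneList, universe: int
) -> dict[str, OverlapResult | int]:
    """Correlated regulation across two conditions, both directions.

    Computes the two reciprocal components — up in A and down in B, and down
    in A and up in B — separately, and reports their summed overlap count.
    """
    c1 = directional_overlap(up_a, down_b, universe)
    c2 = directional_overlap(down_a, up_b, universe)
    return {"up_a_down_b": c1, "down_a_up_b": c2, "n_overlap_total": c1.n_overlap + c2.n_overlap}
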