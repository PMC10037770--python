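"""Marketing-technique codebook, coder assignment, reliability and consensus.

Each advertisement is coded for the presence/absence of 22 persuasive
techniques, counted once per ad regardless of how many products it
features. Ads are distributed randomly among coders; overlapping practice
samples support inter-rater reliability (percent agreement and Cohen's
kappa); disagreements are resolved by majority vote with ties left pending.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import CodingError, ValidationError

#: The 22 technique codes, in codebook order.
TECHNIQUES: tuple[str, ...] = (
    "child_actor",
    "child_product",
    "child_characters",
    "child_language",
    "child_special_effects",
    "child_themes",
    "spokes_characters",
    "parent_child",
    "licensed_characters",
    "cross_promotions",
    "child_incentives",
    "teen_actor",
    "teen_language",
    "teen_music",
    "teen_themes",
    "teen_incentives",
    "teen_humour",
    "contest",
    "celebrity",
    "health_claim",
    "price_promotion",
    "call_to_action_online",
)

_DEFAULT_DEFINITIONS: dict[str, str] = {
    "child_actor": "Main characters are children or have childlike voices",
    "child_product": "Product appeals to children by nature, shape, colour or design",
    "child_characters": "Cartoon, animal or fantasy characters",
    "child_language": "Language commonly used by or directed at children",
    "child_special_effects": "Lettering, animation, music or jingles appealing to children",
    "child_themes": "Fantasy, magic, mystery, adventure or virtual-world themes",
    "spokes_characters": "Brand-owned spokes-characters",
    "parent_child": "Plays on parent-child or authority relationships",
    "licensed_characters": "Licensed entertainment characters",
    "cross_promotions": "Cross-promotion with movies or shows watched by children",
    "child_incentives": "Free gifts, toys or collectibles aimed at children",
    "teen_actor": "Youth 12-17 prominently featured",
    "teen_language": "Adolescent slang or phrasing",
    "teen_music": "Music genres popular with adolescents",
    "teen_themes": "Themes based on adolescent activities or interests",
    "teen_incentives": "Incentives aimed at adolescents",
    "teen_humour": "Adolescent-directed humour",
    "contest": "Contest or sweepstakes with prizes",
    "celebrity": "Celebrity endorsement",
    "health_claim": "Health or nutrition claims",
    "price_promotion": "Price-related premiums or rebates",
    "call_to_action_online": "Sends viewers online to a brand site or app",
}


@dataclass(frozen=True)
class TechniqueCodebook:
    techniques: tuple[str, ...] = TECHNIQUES
    definitions: Mapping[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_DEFINITIONS)
    )

    def __post_init__(self) -> None:
        if len(set(self.techniques)) != len(self.techniques):
            raise ValidationError("technique codes must be unique")
        if len(self.techniques) != 22:
            raise ValidationError(
                f"codebook must hold 22 techniques, got {len(self.techniques)}"
            )


DEFAULT_CODEBOOK = TechniqueCodebook()


@dataclass(frozen=True)
class AdCoding:
    """One coder's presence/absence vector for one ad.

    ``presence`` maps technique -> True/False, or None for a technique left
    pending after an unresolved consensus tie (then listed in ``pending``).
    """

    ad_id: str
    presence: Mapping[str, Optional[bool]]
    coder_id: str
    round: str = "initial"  # or "consensus"
    pending: tuple[str, ...] = ()


@dataclass(frozen=True)
class ReliabilityReport:
    metric: str  # percent_agreement | cohen_kappa
    value: float
    n_items: int
    per_technique: Mapping[str, float]


def assign_ads(
    ad_ids: Sequence[str], n_coders: int, seed: int
) -> dict[int, list[str]]:
    """Randomly partition ads among coders; sizes differ by at most one."""
    if n_coders < 1:
        raise ValidationError(f"n_coders must be >= 1, got {n_coders}")
    rng = np.random.default_rng(seed)
    order = list(ad_ids)
    rng.shuffle(order)
    return {c: order[c::n_coders] for c in range(n_coders)}


def _presence_matrix(
    coding_by_ad: Mapping[str, Mapping[str, bool]], items: Sequence[str],
    techniques: Sequence[str],
) -> np.ndarray:
    mat = np.zeros((len(items), len(techniques)), dtype=bool)
    for i, ad_id in enumerate(items):
        pres = coding_by_ad[ad_id]
        for j, t in enumerate(techniques):
            mat[i, j] = bool(pres.get(t, False))
    return mat


def _pairwise_kappa(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's kappa for two binary ratings of the same items.

    Degenerate marginals: perfect observed agreement gives 1.0; chance
    agreement of 1 with imperfect observation gives 0.0.
    """
    po = float(np.mean(a == b))
    pa1, pb1 = float(np.mean(a)), float(np.mean(b))
    pe = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    if po == 1.0:
        return 1.0
    if pe == 1.0:
        return 0.0
    return (po - pe) / (1.0 - pe)


def interrater_reliability(
    codings_by_coder: Mapping[str, Mapping[str, Mapping[str, bool]]],
    metric: str = "percent_agreement",
    techniques: Sequence[str] = TECHNIQUES,
) -> ReliabilityReport:
    """Inter-rater reliability over the items shared by all coders.

    ``codings_by_coder`` maps coder -> {ad_id -> presence map}. For
    ``percent_agreement`` the headline value is the fraction of items on
    which every coder produced an identical full technique vector; the
    per-technique map holds single-technique agreement rates. For
    ``cohen_kappa`` each technique's value is the mean pairwise kappa and
    the headline value averages over techniques.
    """
    coders = sorted(codings_by_coder)
    if len(coders) < 2:
        raise CodingError("reliability requires at least two coders")
    shared = set.intersection(*(set(codings_by_coder[c]) for c in coders))
    if not shared:
        raise CodingError("coders share no items")
    items = sorted(shared)
    mats = {c: _presence_matrix(codings_by_coder[c], items, techniques) for c in coders}

    if metric == "percent_agreement":
        all_agree = np.ones((len(items), len(techniques)), dtype=bool)
        for a, b in itertools.combinations(coders, 2):
            all_agree &= mats[a] == mats[b]
        per_tech = {
            t: float(np.mean(all_agree[:, j])) for j, t in enumerate(techniques)
        }
        value = float(np.mean(all_agree.all(axis=1)))
    elif metric == "cohen_kappa":
        per_tech = {}
        for j, t in enumerate(techniques):
            kappas = [
                _pairwise_kappa(mats[a][:, j], mats[b][:, j])
                for a, b in itertools.combinations(coders, 2)
            ]
            per_tech[t] = float(np.mean(kappas))
        value = float(np.mean(list(per_tech.values())))
    else:
        raise ValidationError(f"unknown reliability metric {metric!r}")

    return ReliabilityReport(
        metric=metric, value=value, n_items=len(items), per_technique=per_tech
    )


def resolve_consensus(codings: Sequence[AdCoding]) -> AdCoding:
    """Merge several codings of one ad into a consensus record.

    Majority vote per technique; exact ties are left pending (presence None)
    for manual resolution.
    """
    if len(codings) < 2:
        raise CodingError("consensus requires at least two codings")
    ad_ids = {c.ad_id for c in codings}
    if len(ad_ids) != 1:
        raise CodingError(f"codings span multiple ads: {sorted(ad_ids)}")
    techniques = sorted({t for c in codings for t in c.presence})
    presence: dict[str, Optional[bool]] = {}
    pending: list[str] = []
    for t in techniques:
        votes = [bool(c.presence.get(t, False)) for c in codings]
        yes, no = sum(votes), len(votes) - sum(votes)
        if yes > no:
            presence[t] = True
        elif no > yes:
            presence[t] = False
        else:
            presence[t] = None
            pending.append(t)
    return AdCoding(
        ad_id=codings[0].ad_id,
        presence=presence,
        coder_id="consensus",
        round="consensus",
        pending=tuple(pending),
    )
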