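"""Registry of the behavioral items behind the two temperament factors.

Infant biobehavioral testing scores each animal on a small battery of
items over two consecutive days.  Two latent factors summarize them:

* **Activity** — time locomoting (s), time not hanging from the cage top
  or side (s), environmental exploration rate (events/h), and the rare
  dichotomized items ate-food, drank-water and crouching (crouching loads
  negatively: a crouched animal is an inactive one).
* **Emotionality** — cooing rate (events/h), barking rate (events/h) and
  the rare dichotomized items scratched, threats and lipsmacked.

Rare behaviors are recorded 0/1 because most animals never show them.
The registry drives both the default factor loadings used for scoring and
the synthetic-data generator, so simulated cohorts and the scorer always
agree on item names, signs and types.
"""

from __future__ import annotations

import dataclasses

__all__ = ["Item", "ITEMS", "item_names", "factor_items"]

ACTIVITY = "activity"
EMOTIONALITY = "emotionality"


@dataclasses.dataclass(frozen=True)
class Item:
    name: str
    factor: str          # "activity" or "emotionality"
    dichotomous: bool    # rare item recorded 0/1
    sign: int            # loading sign of the item on its factor
    sim_offset: float    # generator: mean on the raw scale
    sim_scale: float     # generator: raw-scale units per latent SD
    sim_noise: float     # generator: item noise SD, in latent-SD units


# Offsets/scales only set the raw units the generator emits (seconds,
# events/h); scoring z-scores every item so they cancel downstream.
# Noise SDs give item-latent correlations of ~0.75-0.85, the reliability
# range typical of scored behavioral batteries.
ITEMS: tuple[Item, ...] = (
    Item("locomotion_s", ACTIVITY, False, +1, 600.0, 150.0, 0.6),
    Item("not_hanging_s", ACTIVITY, False, +1, 1000.0, 200.0, 0.85),
    Item("exploration_rate", ACTIVITY, False, +1, 12.0, 4.0, 0.8),
    Item("ate_food", ACTIVITY, True, +1, 0.0, 1.0, 0.8),
    Item("drank_water", ACTIVITY, True, +1, 0.0, 1.0, 0.8),
    Item("crouching", ACTIVITY, True, -1, 0.0, 1.0, 0.8),
    Item("cooing_rate", EMOTIONALITY, False, +1, 30.0, 10.0, 0.6),
    Item("barking_rate", EMOTIONALITY, False, +1, 4.0, 1.5, 0.8),
    Item("scratched", EMOTIONALITY, True, +1, 0.0, 1.0, 0.8),
    Item("threats", EMOTIONALITY, True, +1, 0.0, 1.0, 0.8),
    Item("lipsmacked", EMOTIONALITY, True, +1, 0.0, 1.0, 0.8),
)


def item_names() -> list[str]:
    return [it.name for it in ITEMS]


def factor_items(factor: str) -> list[Item]:
    return [it for it in ITEMS if it.factor == factor]
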