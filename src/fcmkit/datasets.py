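"""Bundled example data from published participatory mapping studies.

Two small datasets ship with the package:

* **Unmet postpartum care needs (Montreal, Canada)** — net fuzzy
  transitive-closure influences of 20 factors on unmet postpartum care needs
  among recent immigrant women, according to three knowledge sources: a
  published-literature map, family physicians, and birth companions.  Used
  to demonstrate influence-mode correspondence tables and the disagreement
  statistic.

* **Protective factors for maternal health (Guerrero, Mexico)** — the
  standardization lexicon (codes F1-F22) and 12-theme category scheme built
  from maps drawn by two communities of Indigenous traditional midwives.
  The original analysis counted 20 unique factors across the 22 codes (two
  pairs of rows describe facets of one factor); the full coded rows are kept
  here and the count difference is a property of the source tables, not of
  this encoding.
"""

from __future__ import annotations

import pandas as pd

from .model import CategoryScheme, Lexicon

POSTPARTUM_OUTCOME = "Unmet postpartum care needs"

#: factor -> (Literature, Family Physicians, Birth Companions) net influences
_POSTPARTUM_ROWS: list[tuple[str, float, float, float]] = [
    ("Being an Immigrant", 0.2, 0.8, 1.0),
    ("Having a Caesarean Section", 0.2, 0.5, 0.8),
    ("Poverty", 0.4, 0.5, 0.5),
    ("Less Than High School", 0.2, 0.3, 0.0),
    ("Poor relationship with provider", 0.0, 0.5, 0.9),
    ("Provider Workload", 0.0, 0.3, 0.6),
    ("Lack of Respectful Care", 0.0, 0.3, 0.5),
    ("Perceived value of care", 0.0, 0.4, 0.5),
    ("Low Social Support", 0.0, 0.5, 0.5),
    ("Patient Has No Voice", 0.0, 0.3, 0.3),
    ("Perceived Discrimination", 0.0, 0.6, 0.2),
    ("Fragmentation between health and social services", 0.0, 0.5, 0.5),
    ("Lack of multi-disciplinary teams", 0.0, 0.7, 0.0),
    ("Communication Misunderstandings", 0.0, 0.0, 0.6),
    ("Family Responsibilities", 0.0, 0.0, 0.4),
    ("History of Trauma", 0.0, 0.4, 0.0),
    ("Experience of Delivery", 0.0, 0.0, 0.4),
    ("Risk for Depression", 0.0, 0.0, 0.3),
    ("Not Knowing Who to Trust", 0.0, 0.0, 0.3),
    ("Lack of Access to Mental Health Services", 0.0, 0.0, 0.3),
]

POSTPARTUM_SOURCES = ["Literature", "Family Physicians", "Birth Companions"]


def postpartum_net_influences() -> pd.DataFrame:
    """20 factors x 3 knowledge sources of net closure influence on the outcome."""
    frame = pd.DataFrame(
        [row[1:] for row in _POSTPARTUM_ROWS],
        index=[row[0] for row in _POSTPARTUM_ROWS],
        columns=POSTPARTUM_SOURCES,
    )
    frame.index.name = "Factor"
    frame.attrs["outcome"] = POSTPARTUM_OUTCOME
    return frame


# (code, community-1 label, community-2 label, category); empty = not mentioned
_MIDWIFE_ROWS: list[tuple[str, str, str, str]] = [
    ("F1", "The woman is happy",
     "The woman is happy, beautiful, good worker, not lazy, does not get 'coraje'. "
     "Also, she has a healthy husband",
     "The woman has a safe birth and healthy maternity"),
    ("F2", "The woman is strong and brave", "",
     "The woman has a safe birth and healthy maternity"),
    ("F3", "The woman is able to give birth at home",
     "A good childbirth and delivery: healthy pains, less blood loss, fast healing",
     "The woman has a safe birth and healthy maternity"),
    ("F4", "The woman does not get sick",
     "Healthy postpartum: healthy baby/the woman is willing to eat after childbirth",
     "The woman has a safe birth and healthy maternity"),
    ("F5", "Support of a midwife or traditional healer",
     "The woman receives care from the traditional midwife (and she takes care of "
     "the position of the baby)",
     "The woman has support of a traditional midwife or healer"),
    ("F6", "", "Traditional midwives in the community",
     "The woman has support of a traditional midwife or healer"),
    ("F7", "A midwife counsels the husband", "",
     "The woman has support of a traditional midwife or healer"),
    ("F8", "Healthcare centres available", "Hospital available",
     "A healthcare centre or hospital is available"),
    ("F9", "The woman follows protective rituals (lighting candles or indigenous prayers)",
     "The woman follows protective rituals associated with traditional medicine",
     "The woman follows protective rituals"),
    ("F10", "Praying in the church (Christian or Catholic) asking for health", "",
     "The woman follows protective rituals"),
    ("F11", "", "The woman takes care of herself",
     "The woman follows self-care practices"),
    ("F12", "The woman does not suffer violence", "",
     "The woman does not suffer violence"),
    ("F13", "", "The woman lives without worries",
     "The woman lives without worries"),
    ("F14", "", "The woman is well treated by the husband",
     "The woman has a caring, working, and loving husband"),
    ("F15", "The woman has a caring and loving husband",
     "The woman has a caring and working husband",
     "The woman has a caring, working, and loving husband"),
    ("F16", "", "The husband talks to the baby in the womb",
     "The woman has a caring, working, and loving husband"),
    ("F17", "", "Good communication with husband",
     "The woman has good communication with husband"),
    ("F18", "", "The woman discusses (talks) with husband about pregnancy and delivery",
     "The woman has good communication with husband"),
    ("F19", "", "The woman does not get sick",
     "The woman has a good health condition (before pregnancy)"),
    ("F20", "", "The woman heals from her diseases",
     "The woman has a good health condition (before pregnancy)"),
    ("F21", "", "Economic stability",
     "The woman has economic stability"),
    ("F22", "The woman eats good (enough) food", "The woman eats good (enough) food",
     "The woman is well nourished"),
]

MIDWIFE_COMMUNITIES = ("community1", "community2")


def midwife_lexicon() -> Lexicon:
    """Standardization lexicon for the two midwife communities.

    Entries are source-qualified ("community1" / "community2") because one
    raw phrase can code differently per community (the phrase "The woman
    does not get sick" is F4 in community 1 and F19 in community 2).  The
    standard label of each code is its first recorded phrasing.
    """
    lex = Lexicon()
    for code, c1, c2, _cat in _MIDWIFE_ROWS:
        std = c1 or c2
        if c1:
            lex.add(c1, code, std, source="community1")
        if c2:
            lex.add(c2, code, std, source="community2")
        # codes resolve to themselves from any source
        lex.add(code, code, std)
    return lex


def midwife_categories() -> CategoryScheme:
    """12-theme category scheme over the midwife factor codes F1-F22."""
    scheme = CategoryScheme()
    for code, _c1, _c2, cat in _MIDWIFE_ROWS:
        scheme.assign(code, cat)
    return scheme


def midwife_table() -> pd.DataFrame:
    """The raw correspondence rows: code, per-community labels, category."""
    return pd.DataFrame(
        _MIDWIFE_ROWS,
        columns=["standard_code", "community1", "community2", "category"],
    )
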