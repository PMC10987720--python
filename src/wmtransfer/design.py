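"""Construction of recognition-test forms for a pre/post memory-training trial.

A verbal form pairs two 18-word study lists (A and B, three semantic
categories each, one category shared) with two 27-item recognition
conditions: *inclusion* (say "yes" to any studied word) and *exclusion*
(say "yes" only to list-A words; list-B words are intrusion lures).  A
visuospatial form pairs a 20-image study set, each image shown in one of
four quadrants, with a *global* condition (old/new, context irrelevant)
and a *local* condition (same-quadrant/other).  Word selection is driven
by a lexical-availability index with three bands: targets mix one
high-availability word (>25) with mid-band words (10-25), fillers are
high-band, and unstudied lures are low-band (<10) so that false
recognition stays rare.

Every form is materialised once per version: the item order is drawn
from a seed and then frozen, so all participants receive byte-identical
forms.  Two parallel versions exist so that pre-test and post-test can
use different material, with version order counterbalanced across
participants.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConstraintInfeasibleError",
    "LexiconEntry",
    "StudyList",
    "RecognitionForm",
    "VisuospatialStudySet",
    "VERSION_CATEGORIES",
    "default_lexicon",
    "default_image_pool",
    "build_verbal_form",
    "build_spatial_form",
    "counterbalance_versions",
    "forms_to_frame",
]

# Availability bands (availability index units, dimensionless)
HIGH_BAND = 25.0   # fillers and the one "easy" target per category sit above this
MID_LOW = 10.0     # remaining targets sit in [MID_LOW, HIGH_BAND]
# new lures sit strictly below MID_LOW

# Composition constants of the verbal test
N_LIST_WORDS = 18
N_TARGETS_PER_LIST = 12
N_TARGETS_PER_CATEGORY = 4
N_FILLERS = 6
N_TEST_PER_LIST = 6          # per recognition condition: 2 per category
N_NEW_PER_CATEGORY = 3       # per condition, from each of the five categories
N_VERBAL_TEST_ITEMS = 27     # 6 (A) + 6 (B) + 15 (new)

# Composition constants of the visuospatial test
N_IMAGES_STUDY = 20
N_IMAGE_TARGETS = 16         # 4 per quadrant
N_IMAGE_FILLERS = 4          # positions 1, 2, 19, 20
N_GLOBAL_OLD = 6
N_GLOBAL_NEW = 6
N_LOCAL_SAME = 6
N_LOCAL_DIFFERENT = 4
N_LOCAL_NEW = 4

#: Semantic categories per form version.  The last category of each tuple is
#: shared between study lists A and B; the first two belong to list A only
#: and the middle two to list B only.
VERSION_CATEGORIES: dict[int, tuple[str, ...]] = {
    1: ("spices_herbs", "tools", "clothing", "kitchen_utensils", "fruits"),
    2: ("musical_instruments", "furniture", "transports", "building_parts", "animals"),
}


class ConstraintInfeasibleError(ValueError):
    """Raised when a lexicon or image pool cannot satisfy the form composition."""


@dataclass(frozen=True)
class LexiconEntry:
    """One word of the synthetic lexicon.

    Parameters
    ----------
    word_id
        Opaque unique token.
    category
        Semantic category label.
    availability
        Nonnegative lexical-availability index; higher means the word is
        produced more readily when the category is cued.
    """

    word_id: str
    category: str
    availability: float

    def __post_init__(self) -> None:
        if self.availability < 0:
            raise ValueError(f"availability must be >= 0, got {self.availability}")


@dataclass(frozen=True)
class StudyList:
    """An ordered 18-item study list with target/filler roles."""

    list_id: str                     # "A" | "B"
    items: tuple[str, ...]
    roles: tuple[str, ...]           # "target" | "filler" per item
    modality: str = "verbal"
    presentation: str = "oral"       # recorded metadata only (A oral, B visual)

    def __post_init__(self) -> None:
        if len(self.items) != len(self.roles):
            raise ValueError("items and roles must be aligned")

    @property
    def targets(self) -> tuple[str, ...]:
        return tuple(w for w, r in zip(self.items, self.roles) if r == "target")

    @property
    def fillers(self) -> tuple[str, ...]:
        return tuple(w for w, r in zip(self.items, self.roles) if r == "filler")


@dataclass(frozen=True)
class RecognitionForm:
    """A frozen, participant-independent recognition test.

    ``truth`` labels each test item as ``target`` (correct "yes"),
    ``intrusion_lure`` (studied, but from the non-target context) or
    ``new_lure`` (unstudied).  ``layout`` carries the quadrant (1-4) of
    each item for local/visuospatial forms, or ``"center"`` where the
    spatial context is irrelevant; it is ``None`` for verbal forms.
    """

    form_id: str
    modality: str                    # "verbal" | "visuospatial"
    condition: str                   # "inclusion" | "exclusion" | "global" | "local"
    version: int
    test_items: tuple[str, ...]
    truth: tuple[str, ...]
    layout: tuple | None = None
    condition_order: int = 0         # fixed administration order within the test
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.test_items) != len(self.truth):
            raise ValueError("test_items and truth must be aligned")
        if self.layout is not None and len(self.layout) != len(self.test_items):
            raise ValueError("layout must be aligned with test_items")

    def __len__(self) -> int:
        return len(self.test_items)

    def n_with_truth(self, label: str) -> int:
        return sum(t == label for t in self.truth)

    @property
    def has_intrusion_lures(self) -> bool:
        return self.n_with_truth("intrusion_lure") > 0


@dataclass(frozen=True)
class VisuospatialStudySet:
    """Ordered 20-image study sequence with quadrant assignments."""

    images: tuple[str, ...]
    roles: tuple[str, ...]           # "target" | "filler"
    quadrant: tuple[int, ...]        # 1..4 per image
    version: int = 1

    def __post_init__(self) -> None:
        if not (len(self.images) == len(self.roles) == len(self.quadrant)):
            raise ValueError("images, roles and quadrant must be aligned")

    @property
    def targets(self) -> tuple[str, ...]:
        return tuple(i for i, r in zip(self.images, self.roles) if r == "target")

    def study_quadrant(self, image: str) -> int:
        return self.quadrant[self.images.index(image)]


# ---------------------------------------------------------------------------
# Synthetic material pools
# ---------------------------------------------------------------------------

def default_lexicon(
    seed: int = 0,
    n_per_category: int = 80,
    categories: Sequence[str] | None = None,
    mu: float = 2.7,
    sigma: float = 1.0,
) -> list[LexiconEntry]:
    """Generate a synthetic lexicon with log-normal availability indices.

    The default log-normal(mu=2.7, sigma=1.0) places roughly a third of
    the words in each of the three availability bands, so every category
    comfortably supports target, filler and new-lure selection for both
    form versions.  Only the band structure matters downstream; the
    words themselves are opaque tokens.
    """
    if categories is None:
        categories = VERSION_CATEGORIES[1] + VERSION_CATEGORIES[2]
    rng = np.random.default_rng(seed)
    lexicon: list[LexiconEntry] = []
    for cat in categories:
        avail = rng.lognormal(mean=mu, sigma=sigma, size=n_per_category)
        for i, a in enumerate(avail):
            lexicon.append(LexiconEntry(f"{cat}_{i:03d}", cat, float(a)))
    return lexicon


def default_image_pool(version: int = 1, n_images: int = 32) -> list[str]:
    """Opaque ids standing in for hard-to-verbalise geometric figures."""
    return [f"img_v{version}_{i:03d}" for i in range(n_images)]


# ---------------------------------------------------------------------------
# Verbal form construction
# ---------------------------------------------------------------------------

def _band_pools(entries: list[LexiconEntry]) -> dict[str, list[LexiconEntry]]:
    """Split one category into availability bands after removing the three
    most available words (emulating the exclusion of the highest-frequency
    exemplars before selection)."""
    kept = sorted(entries, key=lambda e: -e.availability)[3:]
    return {
        "high": [e for e in kept if e.availability > HIGH_BAND],
        "mid": [e for e in kept if MID_LOW <= e.availability <= HIGH_BAND],
        "low": [e for e in kept if e.availability < MID_LOW],
    }


def _take(pool: list[LexiconEntry], n: int, rng: np.random.Generator,
          category: str, band: str) -> list[str]:
    if len(pool) < n:
        raise ConstraintInfeasibleError(
            f"category {category!r}: need {n} words in availability band "
            f"{band!r}, found {len(pool)}"
        )
    idx = rng.choice(len(pool), size=n, replace=False)
    chosen = [pool[i].word_id for i in sorted(idx)]
    for i in sorted(idx, reverse=True):
        pool.pop(i)
    return chosen


def build_verbal_form(
    lexicon: Iterable[LexiconEntry],
    version: int = 1,
    seed: int = 0,
) -> tuple[StudyList, StudyList, RecognitionForm, RecognitionForm]:
    """Materialise one version of the verbal recognition test.

    Returns study lists A and B plus the inclusion and exclusion
    recognition forms.  Selection honours the availability bands (one
    high-band target per category per list, mid-band for the rest,
    high-band fillers, low-band new lures), the category structure (the
    two lists share exactly one category), and a single seeded
    randomisation of item order that is then frozen.

    Raises
    ------
    ConstraintInfeasibleError
        If some category lacks words in a required availability band.
    """
    rng = np.random.default_rng(seed)
    by_cat: dict[str, list[LexiconEntry]] = {}
    for e in lexicon:
        by_cat.setdefault(e.category, []).append(e)

    wanted = VERSION_CATEGORIES.get(version)
    if wanted is not None and all(c in by_cat for c in wanted):
        cats = list(wanted)
    else:
        cats = sorted(by_cat)[:5]
    if len(cats) < 5:
        raise ConstraintInfeasibleError(
            f"lexicon provides {len(cats)} categories; 5 are required"
        )
    a_only, b_only, shared = cats[:2], cats[2:4], cats[4]
    pools = {c: _band_pools(by_cat[c]) for c in cats}

    # Targets: per list and category one high-band word + 3 mid-band words.
    def pick_targets(cat: str) -> list[str]:
        words = _take(pools[cat]["high"], 1, rng, cat, ">25")
        words += _take(pools[cat]["mid"], N_TARGETS_PER_CATEGORY - 1, rng, cat, "[10,25]")
        return words

    targets_a = {c: pick_targets(c) for c in (*a_only, shared)}
    targets_b = {c: pick_targets(c) for c in (*b_only, shared)}

    # Fillers: six high-band words (2 from a list-A category, 2 from a list-B
    # category, 2 from the shared category), identical in both lists.
    fillers = (
        _take(pools[a_only[0]]["high"], 2, rng, a_only[0], ">25 (filler)")
        + _take(pools[b_only[0]]["high"], 2, rng, b_only[0], ">25 (filler)")
        + _take(pools[shared]["high"], 2, rng, shared, ">25 (filler)")
    )
    filler_order = [fillers[i] for i in rng.permutation(N_FILLERS)]

    def assemble_list(list_id: str, targets: dict[str, list[str]],
                      presentation: str) -> StudyList:
        mids = [w for cat in targets for w in targets[cat]]
        mids = [mids[i] for i in rng.permutation(len(mids))]
        items = filler_order[:3] + mids + filler_order[3:]
        roles = ["filler"] * 3 + ["target"] * N_TARGETS_PER_LIST + ["filler"] * 3
        return StudyList(list_id, tuple(items), tuple(roles), "verbal", presentation)

    list_a = assemble_list("A", targets_a, "oral")
    list_b = assemble_list("B", targets_b, "visual")

    # Recognition conditions use disjoint halves of the targets (2 per
    # category per condition) and disjoint low-band new lures (3 per
    # category per condition).
    def split_tested(targets: dict[str, list[str]]) -> tuple[list[str], list[str]]:
        first, second = [], []
        for cat in targets:
            perm = rng.permutation(N_TARGETS_PER_CATEGORY)
            first += [targets[cat][i] for i in perm[:2]]
            second += [targets[cat][i] for i in perm[2:]]
        return first, second

    a_incl, a_excl = split_tested(targets_a)
    b_incl, b_excl = split_tested(targets_b)
    new_incl = [w for c in cats for w in _take(pools[c]["low"], N_NEW_PER_CATEGORY, rng, c, "<10")]
    new_excl = [w for c in cats for w in _take(pools[c]["low"], N_NEW_PER_CATEGORY, rng, c, "<10")]

    def assemble_form(condition: str, a_words: list[str], b_words: list[str],
                      new_words: list[str], order: int) -> RecognitionForm:
        if condition == "inclusion":
            items = [(w, "target") for w in a_words + b_words]
        else:
            items = [(w, "target") for w in a_words]
            items += [(w, "intrusion_lure") for w in b_words]
        items += [(w, "new_lure") for w in new_words]
        perm = rng.permutation(len(items))
        items = [items[i] for i in perm]
        return RecognitionForm(
            form_id=f"verbal_v{version}_{condition}",
            modality="verbal",
            condition=condition,
            version=version,
            test_items=tuple(w for w, _ in items),
            truth=tuple(t for _, t in items),
            layout=None,
            condition_order=order,
            meta={"categories": tuple(cats), "shared_category": shared},
        )

    inclusion = assemble_form("inclusion", a_incl, b_incl, new_incl, order=1)
    exclusion = assemble_form("exclusion", a_excl, b_excl, new_excl, order=2)
    return list_a, list_b, inclusion, exclusion


# ---------------------------------------------------------------------------
# Visuospatial form construction
# ---------------------------------------------------------------------------

def build_spatial_form(
    image_pool: Sequence[str],
    version: int = 1,
    seed: int = 0,
) -> tuple[VisuospatialStudySet, RecognitionForm, RecognitionForm]:
    """Materialise one version of the visuospatial recognition test.

    The 20-image study set carries 16 targets (exactly 4 per quadrant)
    and 4 fillers at positions 1, 2, 19, 20.  The global condition shows
    6 old + 6 new images centred on the sheet; the local condition shows
    6 old images in their study quadrant, 4 old images in a different
    quadrant and 4 new images.  The 16 targets are partitioned across
    the two conditions so no target is tested twice.
    """
    pool = list(dict.fromkeys(image_pool))
    needed = N_IMAGES_STUDY + N_GLOBAL_NEW + N_LOCAL_NEW
    if len(pool) < needed:
        raise ConstraintInfeasibleError(
            f"image pool has {len(pool)} distinct images; {needed} are required "
            f"({N_IMAGES_STUDY} studied + {N_GLOBAL_NEW + N_LOCAL_NEW} new)"
        )
    rng = np.random.default_rng(seed)
    chosen = [pool[i] for i in rng.choice(len(pool), size=needed, replace=False)]
    targets, fillers = chosen[:N_IMAGE_TARGETS], chosen[N_IMAGE_TARGETS:N_IMAGES_STUDY]
    new_global = chosen[N_IMAGES_STUDY:N_IMAGES_STUDY + N_GLOBAL_NEW]
    new_local = chosen[N_IMAGES_STUDY + N_GLOBAL_NEW:]

    # Quadrants: exactly 4 targets per quadrant, seeded shuffle breaks ties.
    quad_assign = {}
    perm = rng.permutation(N_IMAGE_TARGETS)
    for slot, i in enumerate(perm):
        quad_assign[targets[i]] = slot % 4 + 1
    for f in fillers:
        quad_assign[f] = int(rng.integers(1, 5))

    mid = [targets[i] for i in rng.permutation(N_IMAGE_TARGETS)]
    images = fillers[:2] + mid + fillers[2:]
    roles = ["filler"] * 2 + ["target"] * N_IMAGE_TARGETS + ["filler"] * 2
    study = VisuospatialStudySet(
        images=tuple(images),
        roles=tuple(roles),
        quadrant=tuple(quad_assign[i] for i in images),
        version=version,
    )

    # Partition targets across conditions: 6 global-old, 6 local-same, 4 local-diff.
    perm = rng.permutation(N_IMAGE_TARGETS)
    g_old = [targets[i] for i in perm[:N_GLOBAL_OLD]]
    l_same = [targets[i] for i in perm[N_GLOBAL_OLD:N_GLOBAL_OLD + N_LOCAL_SAME]]
    l_diff = [targets[i] for i in perm[N_GLOBAL_OLD + N_LOCAL_SAME:]]

    g_items = [(i, "target", "center") for i in g_old]
    g_items += [(i, "new_lure", "center") for i in new_global]
    perm = rng.permutation(len(g_items))
    g_items = [g_items[i] for i in perm]
    global_form = RecognitionForm(
        form_id=f"spatial_v{version}_global",
        modality="visuospatial",
        condition="global",
        version=version,
        test_items=tuple(i for i, _, _ in g_items),
        truth=tuple(t for _, t, _ in g_items),
        layout=tuple(q for _, _, q in g_items),
        condition_order=1,
    )

    def other_quadrant(img: str) -> int:
        options = [q for q in (1, 2, 3, 4) if q != quad_assign[img]]
        return int(options[rng.integers(0, 3)])

    l_items = [(i, "target", quad_assign[i]) for i in l_same]
    l_items += [(i, "intrusion_lure", other_quadrant(i)) for i in l_diff]
    l_items += [(i, "new_lure", int(rng.integers(1, 5))) for i in new_local]
    perm = rng.permutation(len(l_items))
    l_items = [l_items[i] for i in perm]
    local_form = RecognitionForm(
        form_id=f"spatial_v{version}_local",
        modality="visuospatial",
        condition="local",
        version=version,
        test_items=tuple(i for i, _, _ in l_items),
        truth=tuple(t for _, t, _ in l_items),
        layout=tuple(q for _, _, q in l_items),
        condition_order=2,
        meta={"study_quadrant": {i: quad_assign[i] for i in l_same + l_diff}},
    )
    return study, global_form, local_form


# ---------------------------------------------------------------------------
# Counterbalancing
# ---------------------------------------------------------------------------

def counterbalance_versions(
    participants: Sequence, seed: int = 0
) -> dict[object, tuple[int, int]]:
    """Assign (pretest_version, posttest_version) orders as evenly as possible.

    Half the participants (rounding down) receive versions (1, 2) and the
    rest (2, 1); which participants get which order is a seeded shuffle.
    """
    ids = list(participants)
    if not ids:
        raise ValueError("at least one participant is required")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    half = len(ids) // 2
    out: dict[object, tuple[int, int]] = {}
    for rank, i in enumerate(perm):
        out[ids[i]] = (1, 2) if rank < half else (2, 1)
    return out


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def forms_to_frame(forms: Iterable[RecognitionForm]) -> pd.DataFrame:
    """Flatten recognition forms to one row per test item."""
    rows = []
    for form in forms:
        layout = form.layout or [""] * len(form)
        for pos, (item, truth, quad) in enumerate(
            zip(form.test_items, form.truth, layout), start=1
        ):
            rows.append(
                {
                    "form_id": form.form_id,
                    "modality": form.modality,
                    "condition": form.condition,
                    "version": form.version,
                    "position": pos,
                    "item_id": item,
                    "truth": truth,
                    "quadrant": quad,
                }
            )
    return pd.DataFrame(rows)
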