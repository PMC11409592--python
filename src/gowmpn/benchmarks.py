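"""Reference benchmark scores for six-task pathology-report extraction.

Published micro/macro-averaged F1 scores for multi-task (MT) and single-task
(ST) message-passing graph-of-words models and an MT-CNN baseline, measured on
a restricted SEER-registry benchmark (site, subsite, laterality, histology,
behavior, grade).  The underlying corpus is not publicly shareable, so these
per-task scores serve as fixed inputs for exercising the 12-score aggregate
statistic, not as quantities this package can recompute.

Each row is keyed by (architecture, dropout, word distance d, mini-batch
size); ``d`` is None where windowed co-occurrence does not apply.  Scores are
ordered (micro, macro) per task in task order.
"""

TASKS = ("site", "subsite", "laterality", "histology", "behavior", "grade")

REFERENCE_SCORES: dict[tuple[str, float, int | None, int], tuple[float, ...]] = {
    ("MT", 0.0, 2, 64):     (0.9292, 0.6553, 0.6552, 0.2869, 0.9149, 0.5162,
                             0.7781, 0.2913, 0.9730, 0.8873, 0.7642, 0.6197),
    ("MT", 0.0, 2, 256):    (0.9260, 0.6727, 0.6444, 0.3008, 0.9096, 0.5149,
                             0.7752, 0.3219, 0.9726, 0.8907, 0.7467, 0.6411),
    ("MT", 0.0, 5, 64):     (0.9298, 0.6762, 0.6521, 0.3072, 0.9145, 0.5159,
                             0.7782, 0.3197, 0.9731, 0.8899, 0.7624, 0.6538),
    ("MT", 0.0, 5, 256):    (0.9267, 0.6747, 0.6424, 0.3069, 0.9098, 0.5141,
                             0.7783, 0.3240, 0.9735, 0.8909, 0.7536, 0.6556),
    ("MT", 0.0, 10, 64):    (0.9277, 0.6704, 0.6528, 0.2981, 0.9156, 0.5173,
                             0.7788, 0.3137, 0.9728, 0.8778, 0.7654, 0.6677),
    ("MT", 0.0, 10, 256):   (0.9279, 0.6696, 0.6464, 0.3097, 0.9113, 0.5254,
                             0.7765, 0.3363, 0.9720, 0.8547, 0.7541, 0.6380),
    ("MT", 0.25, 2, 256):   (0.9306, 0.6738, 0.6548, 0.3073, 0.9147, 0.5136,
                             0.7798, 0.2949, 0.9737, 0.8758, 0.7649, 0.6726),
    ("MT", 0.25, 5, 256):   (0.9307, 0.6834, 0.6534, 0.2967, 0.9145, 0.5081,
                             0.7792, 0.3073, 0.9739, 0.8932, 0.7630, 0.6608),
    ("MT", 0.25, 10, 256):  (0.9306, 0.6768, 0.6548, 0.3049, 0.9150, 0.5204,
                             0.7802, 0.3391, 0.9739, 0.8925, 0.7627, 0.6653),
    ("ST", 0.25, 10, 256):  (0.9310, 0.6571, 0.6532, 0.3045, 0.9143, 0.5085,
                             0.7785, 0.3183, 0.9739, 0.8797, 0.7567, 0.6600),
    ("MT-CNN", 0.25, None, 256): (0.9250, 0.6754, 0.6538, 0.3208, 0.9000, 0.5083,
                                  0.7651, 0.3642, 0.9652, 0.8700, 0.7401, 0.6345),
}
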