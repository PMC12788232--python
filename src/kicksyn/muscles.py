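"""Channel registry for the 15-muscle side-kick montage.

Twelve muscles are recorded on the kicking (left) side and three on the
supporting (right) side, marked with an ``R`` suffix.  The tuple order is the
canonical column order of every trial CSV and activation matrix in this
package.
"""

MUSCLES: tuple[str, ...] = (
    "BR",    # brachioradialis
    "BB",    # biceps brachii
    "TB",    # triceps brachii
    "AD",    # anterior deltoid
    "EO",    # external oblique
    "GM",    # gluteus maximus
    "GMed",  # gluteus medius
    "BF",    # biceps femoris
    "RF",    # rectus femoris
    "VL",    # vastus lateralis
    "TA",    # tibialis anterior
    "GAS",   # gastrocnemius, medial head
    "TAR",   # tibialis anterior, supporting leg
    "GMR",   # gluteus maximus, supporting leg
    "RFR",   # rectus femoris, supporting leg
)

#: Conditioning protocols of the crossover design:
#: ESG = squat + neuromuscular electrical stimulation,
#: RBG = resistance-band lateral steps, SQG = heavy barbell squat.
PROTOCOLS: tuple[str, ...] = ("ESG", "RBG", "SQG")

#: Post-intervention vertical-jump assessment times (minutes).
TIME_POINTS_MIN: tuple[int, ...] = (6, 8, 10)

#: Movement-cycle phase marks: a–b preparation, b–c knee lift,
#: c–d kick, d–e recovery.
PHASE_MARKS: tuple[str, ...] = ("a", "b", "c", "d", "e")
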