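"""Degenerate-primer arithmetic on the published broad-range hgcAB set.

Builds the three published primers, reports their degeneracy (number of
concrete oligos in the mixture), the equal-distribution occurrence
threshold, nearest-neighbor melting ranges, and reproduces the reverse
primer redesign as three positional edits.
"""

from degenamp.insilico import apply_edits, equal_distribution_threshold
from degenamp.primers import degeneracy, expand, melting_range, reverse_complement
from degenamp.simulate import FORWARD_PRIMER, REVERSE_PRIMER_32, REVERSE_PRIMER_96

for primer in (FORWARD_PRIMER, REVERSE_PRIMER_96, REVERSE_PRIMER_32):
    d = degeneracy(primer)
    t_min, t_max = melting_range(primer)
    print(
        f"{primer.name:8s} {primer.sequence}  degeneracy={d:3d} "
        f"equal-use threshold={equal_distribution_threshold(d):5.2f}%  "
        f"Tm {t_min:.1f}-{t_max:.1f} C"
    )
# degeneracy = concrete oligos in the synthesized mixture; the threshold
# is the percent occurrence each oligo would have if all amplified equally

first = expand(REVERSE_PRIMER_32)[0]
print(f"\nfirst enumerated variant: {first.id} = {first.sequence}")
print(f"reverse complement of {REVERSE_PRIMER_32.name}: "
      f"{reverse_complement(REVERSE_PRIMER_32.sequence)}")

report = apply_edits(REVERSE_PRIMER_96, {3: "G", 9: "G", 15: "S"})
print(
    f"\nredesign via edits 3:G 9:G 15:S -> {report.primer.sequence} "
    f"(degeneracy {report.degeneracy_before} -> {report.degeneracy_after})"
)
# the three 5'-side edits remove mixture members unseen in nature while
# keeping the 3' end fully degenerate
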