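"""Reference compound structures used in documentation and calibration.

Cloperastine is a centrally acting cough suppressant derived from the
antihistamine diphenhydramine; the pair is the canonical illustration of a
fingerprint-similarity target hit (cloperastine picks up the histamine H1
receptor through its neighbor diphenhydramine). The third structure,
1-[2-(4-benzylphenoxy)ethyl]piperidine, is a micromolar inhibitor of
leukotriene A4 hydrolase from the benzylphenoxy-alkylamine series: it shares
nearly all of cloperastine's pieces (chlorine aside) wired differently —
conceptually, cloperastine broken at its ether group with the
piperidine-bearing chain reattached to the ring system — which makes the
pair the canonical illustration of a *fragment-level* MCS hit that path
fingerprints undervalue. The MCS normalization default was calibrated on
this pair (see docs/methods.md).
"""

CLOPERASTINE = "Clc1ccc(cc1)C(OCCN1CCCCC1)c1ccccc1"
DIPHENHYDRAMINE = "CN(C)CCOC(c1ccccc1)c1ccccc1"
LTA4H_INHIBITOR = "C(c1ccccc1)c1ccc(OCCN2CCCCC2)cc1"
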