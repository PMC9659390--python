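"""Reference reporter sequences.

mNeonGreen is the 236-residue green fluorescent protein engineered from
*Branchiostoma lanceolatum* LanYFP (Shaner et al., 2013), widely used as a
fusion reporter in trypanosome protein tagging. Tagging constructs append
short linker residues, so the expressed reporter open reading frame is
typically a residue or two longer than the fluorophore itself.
"""

MNEONGREEN = (
    "MVSKGEEDNMASLPATHELHIFGSINGVDFDMVGQGTGNPNDGYEELNLKSTKGDLQFSPWILVPHIGYGF"
    "HQYLPYPDGMSPFQAAMVDGSGYQVHRTMQFEDGASLTVNYRYTYEGSHIKGEAQVKGTGFPADGPVMTNS"
    "LTAADWCRSKKTYPNDKTIISTFKWSYTTGNGKRYRSTARTTYTFAKPMAANYLKNQPMYVFRKTELKHSK"
    "TELNFKEWQKAFTDVMGMDELYK"
)
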