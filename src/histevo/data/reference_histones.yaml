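# Packaged reference histones (editable).
#
# Sequences are mature (initiator-Met-cleaved) canonical core histones for
# Homo sapiens and Saccharomyces cerevisiae. Fold spans are 1-based
# inclusive coordinates on each reference; by convention the fold begins
# immediately after the N-terminal tail, so fold_start - 1 is the NTD
# length. The human H2A NTD is the 22-residue mature tail (fold starts at
# position 23); the yeast H2A NTD has 23 residues (fold starts at 24).
#
# Variant references are decoys used by the variant filter: a sequence
# strictly closer (global percent identity) to a variant reference than to
# the canonical reference is flagged as a variant. The "macroh2a_like" and
# "h3_variant_like" entries are synthetic decoys built from the canonical
# sequence (long acidic C-terminal extension / diverged N-terminal
# extension); "h2az_like" follows the human H2A.Z N-terminal architecture.
H2A:
  human: SGRGKQGGKTRAKAKSRSSRAGLQFPVGRVHRLLRKGNYAERVGAGAPVYLAAVLEYLTAEILELAGNAARDNKKTRIIPRHLQLAIRNDEELNKLLGRVTIAQGGVLPNIQAVLLPKKTESHHKAKGK
  human_fold_span: [23, 95]
  yeast: SGGKGGKAGSAAKASQSRSAKAGLTFPVGRVHRLLRRGNYAQRIGSGAPVYLTAVLEYLAAEILELAGNAARDNKKTRIIPRHLQLAIRNDDELNKLLGNVTIAQGGVLPNIHQNLLPKKSAKATKASQEL
  yeast_fold_span: [24, 96]
  variants:
    h2az_like: AGGKAGKDSGKAKTKAVSRSQRAGLQFPVGRIHRHLKSRTTSHGRVGATAAVYSAAILEYLTAEVLELAGNASKDLKVKRITPRHLQLAIRGDEELDSLIKATIAGGGVIPHIHKSLIGKKGQQKTV
    macroh2a_like: SGRGKQGGKTRAKAKSRSSRAGLQFPVGRVHRLLRKGNYAERVGAGAPVYLAAVLEYLTAEILELAGNAARDNKKTRIIPRHLQLAIRNDEELNKLLGRVTIAQGGVLPNIQAVLLPKKTESHHKAKGKEDEEDSEDEEGDESDGEKDEDSEEDGEDEESEDDEGSEDE
H2B:
  human: PEPAKSAPAPKKGSKKAVTKAQKKDGKKRKRSRKESYSVYVYKVLKQVHPDTGISSKAMGIMNSFVNDIFERIAGEASRLAHYNKRSTITSREIQTAVRLLLPGELAKHAVSEGTKAVTKYTSSK
  human_fold_span: [36, 125]
  yeast: SAKAEKKPASKAPAEKKPAAKKTSTSTDGKKRSKARKETYSSYIYKVLKQTHPDTGISQKSMSILNSFVNDIFERIATEASKLAAYNKKSTISAREIQTAVRLILPGELAKHAVSEGTRAVTKYSSSTQA
  yeast_fold_span: [38, 130]
  variants: {}
H3:
  human: ARTKQTARKSTGGKAPRKQLATKAARKSAPATGGVKKPHRYRPGTVALREIRRYQKSTELLIRKLPFQRLVREIAQDFKTDLRFQSSAVMALQEACEAYLVGLFEDTNLCAIHAKRVTIMPKDIQLARRIRGERA
  human_fold_span: [39, 135]
  yeast: ARTKQTARKSTGGKAPRKQLASKAARKSAPSTGGVKKPHRYKPGTVALREIRRFQKSTELLIRKLPFQRLVREIAQDFKTDLRFQSSAIGALQESVEAYLVSLFEDTNLAAIHAKRVTIQKKDIKLARRLRGERS
  yeast_fold_span: [39, 135]
  variants:
    h3_variant_like: MGPRRRSRKPEAPRRRSPSPGPSRRGPSLGASARTKQTARKSTGGKAPRKQLATKVARKSAPATGGVKKPHRYRPGTVALREIRRYQKSTHLLIRKLPFSRLAREICVKFTRGVDLRFQSSAVMALQEAAEAFLVHLFEDAYLLTLHAGRVTLFPKDVQLARRIRGLEE
H4:
  human: SGRGKGGKGLGKGGAKRHRKVLRDNIQGITKPAIRRLARRGGVKRISGLIYEETRGVLKVFLENVIRDAVTYTEHAKRKTVTAMDVVYALKRQGRTLYGFGG
  human_fold_span: [25, 102]
  yeast: SGRGKGGKGLGKGGAKRHRKILRDNIQGITKPAIRRLARRGGVKRISGLIYEEVRAVLKSFLESVIRDSVTYTEHAKRKTVTSLDVVYALKRQGRTLYGFGG
  yeast_fold_span: [25, 102]
  variants: {}
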