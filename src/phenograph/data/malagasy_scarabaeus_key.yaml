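name: Identification key to adult Malagasy Scarabaeus
root: 1
couplets:
  1:
    - text: >-
        Pronotal punctuation strong, granulose and very dense (punctures
        separated by 1 puncture diameter or less). Colour metallic bronze
        to coppery
      taxon: Scarabaeus radama
    - text: >-
        Pronotal punctuation weaker, simple and much sparser (punctures
        separated by 5 diameters or more). Colour black
      couplet: 2
  2:
    - text: >-
        Wings reduced, elytra narrower than pronotum. Distal end of male
        protibia curved. Female head without tubercles
      taxon: Scarabaeus sevoistra
    - text: >-
        Wings fully developed, elytra as wide or slightly wider than
        pronotum. Distal end of male protibia straight. Female head with a
        frontal tubercle
      couplet: 3
  3:
    - text: >-
        Anterolateral angle of pronotum directed laterally. Female head
        tubercle sinuated medially. Ventral margin of male protibia
        expanded. Parameres less slender, apex forming a straight angle
        with dorso-distal margin in lateral view
      taxon: Scarabaeus sakalava
      figures: [Fig. 3a, Fig. 3c, Fig. 3e, Fig. 4a]
    - text: >-
        Anterolateral angle of pronotum directed obliquely forward. Female
        head tubercle conical. Ventral margin of male protibia poorly
        expanded. Parameres more slender, apex creating an obtuse angle
        with dorso-distal margin in lateral view
      taxon: Scarabaeus viettei
      figures: [Fig. 3b, Fig. 3d, Fig. 3f, Fig. 4b]
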