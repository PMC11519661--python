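prefixes:
  AISM: http://purl.obolibrary.org/obo/AISM_
  COLAO: http://purl.obolibrary.org/obo/COLAO_
  PATO: http://purl.obolibrary.org/obo/PATO_
  RO: http://purl.obolibrary.org/obo/RO_
  BFO: http://purl.obolibrary.org/obo/BFO_
  UO: http://purl.obolibrary.org/obo/UO_
terms:
- token: aism-male_organism
- token: aism-chitin_based_cuticle
  label: chitin-based cuticle
- token: aism-lateral_side
- token: aism-cuticular_seta
- token: aism-ventral_side
- token: aism-antenna_with_9_antennomeres
- token: colao-antennal_club
  id: '0000267'
- token: aism-flagellomere_5
- token: aism-flagellomere_6
- token: aism-flagellomere_7
- token: aism-insect_leg
- token: aism-genal_margin
- token: aism-posterior_region
- token: aism-anterior_region
- token: aism-head_margin_at_genoclypeal_sulcus
- token: aism-lateral_clypeal_tooth_1
- token: aism-lateral_clypeal_tooth_2
- token: aism-clypeal_margin_between_clypeal_teeth_1
- token: aism-clypeal_margin_between_clypeal_teeth_1_and_2
- token: aism-frons
- token: aism-cuticular_carina
- token: aism-vertex
- token: aism-granulated_cuticle
- token: aism-gena
- token: aism-medial_region
- token: aism-lateral_region
- token: aism-clypeus
- token: aism-glossa
- token: aism-epipharynx
- token: aism-insect_maxilla
- token: aism-maxillary_palpus_with_4_palpomeres
- token: aism-labial_palpus_with_3_palpomeres
- token: aism-pronotum
- token: aism-dorsal_region
- token: aism-lateral_margin
- token: aism-posterior_margin
- token: aism-row_of_punctures
- token: aism-anterolateral_pronotal_angle
- token: aism-lateral_pronotal_carina
- token: aism-pronotal_disc
- token: aism-punctate_cuticle
- token: aism-cuticular_puncture
- token: aism-elytron_with_9_striae
- token: aism-elytral_interstria
- token: aism-cuticular_granule
- token: aism-elytral_interstria_8
- token: aism-proximal_region
- token: aism-elytral_stria_7
- token: aism-elytral_interstria_9
- token: aism-elytral_stria_8
- token: aism-scutellar_shield
- token: aism-hind_wing
- token: aism-abdomen_with_8_sternites
- token: aism-abdominal_sternite_viii
  label: abdominal sternite VIII
- token: aism-cuticular_groove
- token: aism-postero_lateral_margin
  label: postero-lateral margin
- token: aism-abdominal_tergite_viii
  label: abdominal tergite VIII
- token: aism-anterior_groove_of_tergite_viii
  label: anterior groove of tergite VIII
- token: aism-anterior_carina_of_tergite_viii
  label: anterior carina of tergite VIII
- token: aism-distal_border_of_tergite_viii
  label: distal border of tergite VIII
- token: aism-protarsus_with_5_protarsomeres
- token: aism-mesotarsus_with_5_mesotarsomeres
- token: aism-metatarsus_with_5_metatarsomeres
- token: aism-protibia
- token: aism-dorsal_protibial_cuticular_tooth_1
- token: aism-dorsal_protibial_cuticular_tooth_2
- token: aism-dorsal_protibial_cuticular_tooth_3
- token: aism-dorsal_protibial_cuticular_tooth_4
- token: aism-ventral_margin
- token: aism-dorsal_protibial_margin_between_protibial_teeth_1_and_2
- token: aism-dorsal_protibial_margin_between_protibial_teeth_2_and_3
- token: aism-dorsal_protibial_margin_between_protibial_teeth_3_and_4
- token: aism-profemur
- token: aism-antero_ventral_margin
  label: antero-ventral margin
- token: aism-distal_region
- token: aism-cuticular_spine
  id: '0000527'
- token: aism-mesotibia
- token: aism-mesotibial_spur
- token: aism-mesotibial_carina
- token: aism-metatibia
- token: aism-metatibial_spur
  id: '0000040'
- token: aism-metatibial_carina
- token: aism-mesofemur
- token: aism-simple_setigerous_cuticular_puncture
- token: aism-dorsal_margin
- token: aism-mesotibial_posteroventral_carina
- token: aism-mesotibial_anteroventral_carina
- token: aism-mesotibial_anterodorsal_carina
- token: aism-mesotibial_posterodorsal_carina
- token: aism-metafemur
- token: aism-metatibial_posteroventral_carina
- token: aism-punctures
- token: aism-row
- token: aism-metatibial_anteroventral_carina
- token: aism-metatibial_anterodorsal_carina
- token: aism-metatibial_posterodorsal_carina
- token: aism-parameres
- token: aism-left_paramere
- token: aism-cuticular_protrusion
- token: aism-frontolateral_peripheral_endophallite
- token: aism-axial_endophallite
- token: aism-subaxial_endophallite
- token: aism-superior_right_peripheral_endophallite
- token: aism-raspula
- token: aism-posterior_longitudinal_hypomeral_carina
- token: aism-anterior_hypomeral_carina
- token: aism-lamella_copulatrix
- token: pato-ovate
- token: pato-red_brown
- token: pato-black
- token: pato-glistening
- token: pato-present
- token: pato-right_angle_to
- token: pato-protruding
- token: pato-acute_angle_to
- token: pato-notched
- token: pato-bilaterally_paired
- token: pato-transverse_orientation
- token: pato-decreased_length
- token: pato-wrinkled
- token: pato-convex
- token: pato-curved
- token: pato-sharp
- token: pato-lateral_orientation
- token: pato-serrated
- token: pato-sparse
- token: pato-microreticulate
- token: pato-decreased_size
- token: pato-flattened
- token: pato-concealed
- token: pato-normal
- token: pato-multiple
- token: pato-increased_length
- token: pato-scalloped
- token: pato-concave
- token: pato-obtuse
- token: pato-straight_angle_to
- token: pato-dorso_ventrally_flattened
  label: dorso-ventrally flattened
- token: pato-asymmetrical
- token: pato-elongated
- token: pato-ring_shaped
- token: pato-absent
- token: pato-oblique_orientation
- token: pato-obtuse_angle_to
- token: uo-millimeter
  id: '0000022'
- token: ro-in_homology_relationship_with
  relation: true
- token: ro-adjacent_to
  relation: true
- token: ro-coincident_with
  relation: true
- token: ro-encircles
  relation: true
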