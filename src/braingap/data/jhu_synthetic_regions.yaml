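# Synthetic reconstruction of the JHU-atlas region groupings.
# Printed region sizes (hemispheres 94/94, domain-general 8/8,
# language-specific 9/9, frontal 16/16, temporal 13/13, parietal 6/6,
# occipital 5/5) are faithful; parcel names are representative.
regions:
  hemisphere:
    left: &id001
    - superior_frontal_gyrus
    - middle_frontal_gyrus_dpfc
    - middle_frontal_gyrus_orbital
    - inferior_frontal_gyrus_opercularis
    - inferior_frontal_gyrus_orbitalis
    - inferior_frontal_gyrus_triangularis
    - precentral_gyrus
    - lateral_fronto_orbital_gyrus
    - middle_fronto_orbital_gyrus
    - gyrus_rectus
    - supplementary_motor_area
    - frontal_pole
    - medial_frontal_gyrus
    - paracentral_lobule
    - central_operculum
    - frontal_operculum
    - superior_temporal_gyrus
    - posterior_superior_temporal_gyrus
    - middle_temporal_gyrus
    - posterior_middle_temporal_gyrus
    - inferior_temporal_gyrus
    - posterior_inferior_temporal_gyrus
    - fusiform_gyrus
    - parahippocampal_gyrus
    - entorhinal_area
    - temporal_pole
    - heschl_gyrus
    - planum_temporale
    - planum_polare
    - postcentral_gyrus
    - superior_parietal_lobule
    - supramarginal_gyrus
    - angular_gyrus
    - precuneus
    - parietal_operculum
    - superior_occipital_gyrus
    - middle_occipital_gyrus
    - inferior_occipital_gyrus
    - cuneus
    - lingual_gyrus
    - insular
    - anterior_cingulate_gyrus
    - middle_cingulate_gyrus
    - posterior_cingulate_gyrus
    - retrosplenial_cortex
    - hippocampus
    - amygdala
    - olfactory_area
    - caudate_nucleus
    - putamen
    - globus_pallidus
    - thalamus
    - nucleus_accumbens
    - substantia_nigra
    - red_nucleus
    - mammillary_body
    - hypothalamus
    - basal_forebrain
    - corticospinal_tract
    - cerebral_peduncle
    - anterior_limb_of_internal_capsule
    - posterior_limb_of_internal_capsule
    - retrolenticular_part_of_internal_capsule
    - anterior_corona_radiata
    - superior_corona_radiata
    - posterior_corona_radiata
    - posterior_thalamic_radiation
    - sagittal_stratum
    - external_capsule
    - cingulum_cingulate_part
    - cingulum_hippocampal_part
    - fornix_cres
    - stria_terminalis
    - superior_longitudinal_fasciculus
    - inferior_longitudinal_fasciculus
    - inferior_fronto_occipital_fasciculus
    - uncinate_fasciculus
    - superior_fronto_occipital_fasciculus
    - tapetum
    - medial_lemniscus
    - inferior_cerebellar_peduncle
    - superior_cerebellar_peduncle
    - optic_tract
    - optic_radiation
    - anterior_thalamic_radiation
    - corticopontine_tract
    - frontal_white_matter
    - parietal_white_matter
    - temporal_white_matter
    - occipital_white_matter
    - periventricular_white_matter
    - genu_of_corpus_callosum
    - body_of_corpus_callosum
    - splenium_of_corpus_callosum
    right: *id001
  domain_general:
    left: &id002
    - superior_frontal_gyrus
    - middle_frontal_gyrus_dpfc
    - inferior_frontal_gyrus_orbitalis
    - precentral_gyrus
    - posterior_cingulate_gyrus
    - supramarginal_gyrus
    - angular_gyrus
    - insular
    right: *id002
  language_specific:
    left: &id003
    - inferior_frontal_gyrus_opercularis
    - inferior_frontal_gyrus_triangularis
    - superior_temporal_gyrus
    - posterior_superior_temporal_gyrus
    - middle_temporal_gyrus
    - posterior_middle_temporal_gyrus
    - heschl_gyrus
    - planum_temporale
    - temporal_pole
    right: *id003
  frontal:
    left: &id004
    - superior_frontal_gyrus
    - middle_frontal_gyrus_dpfc
    - middle_frontal_gyrus_orbital
    - inferior_frontal_gyrus_opercularis
    - inferior_frontal_gyrus_orbitalis
    - inferior_frontal_gyrus_triangularis
    - precentral_gyrus
    - lateral_fronto_orbital_gyrus
    - middle_fronto_orbital_gyrus
    - gyrus_rectus
    - supplementary_motor_area
    - frontal_pole
    - medial_frontal_gyrus
    - paracentral_lobule
    - central_operculum
    - frontal_operculum
    right: *id004
  temporal:
    left: &id005
    - superior_temporal_gyrus
    - posterior_superior_temporal_gyrus
    - middle_temporal_gyrus
    - posterior_middle_temporal_gyrus
    - inferior_temporal_gyrus
    - posterior_inferior_temporal_gyrus
    - fusiform_gyrus
    - parahippocampal_gyrus
    - entorhinal_area
    - temporal_pole
    - heschl_gyrus
    - planum_temporale
    - planum_polare
    right: *id005
  parietal:
    left: &id006
    - postcentral_gyrus
    - superior_parietal_lobule
    - supramarginal_gyrus
    - angular_gyrus
    - precuneus
    - parietal_operculum
    right: *id006
  occipital:
    left: &id007
    - superior_occipital_gyrus
    - middle_occipital_gyrus
    - inferior_occipital_gyrus
    - cuneus
    - lingual_gyrus
    right: *id007
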