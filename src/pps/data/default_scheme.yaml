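# Default synoptic placental-pathology scoring scheme.
#
# Every lesion is scored either on a binary scale (0 = absent, 1 = present)
# or a graded linear scale (0 = absent, 1 = focal, 2 = patchy, 3 = diffuse).
# Lesions are grouped into etiological categories; a category's severity is
# the sum of its member-lesion grades, capped at the category max_score.
#
# The category caps are fixed by the synoptic evaluation form this scheme
# encodes. The per-lesion scale assignment is chosen so that member
# max-grades reach each cap exactly (for MVM the member grades sum to 15 and
# the cap of 14 binds, because retroplacental hematoma is carried as a
# binary MVM member). Lesions marked "cap-completing" are standard synoptic
# form items not broken out in the study's frequency table; they are needed
# for the chorioamnionitis cap of 11 to be attainable. Edit freely: the
# loader validates structure, not this particular assignment.
version: "1.0"

categories:
  - category_id: MVM
    display_name: Maternal vascular malperfusion
    max_score: 14
  - category_id: implantation_site
    display_name: Implantation site abnormalities
    max_score: 4
  - category_id: chorioamnionitis
    display_name: Histological chorioamnionitis
    max_score: 11
  - category_id: villous_maldevelopment
    display_name: Placental villous maldevelopment
    max_score: 5
  - category_id: fetal_vascular_malperfusion
    display_name: Fetal vascular malperfusion
    max_score: 6
  - category_id: interface_disturbance
    display_name: Maternal-fetal interface disturbance
    max_score: 5
  - category_id: chronic_inflammation
    display_name: Chronic inflammation
    max_score: 6

lesions:
  # --- maternal vascular malperfusion ---
  - lesion_id: infarction
    display_name: Placental infarction
    category_id: MVM
    scale: graded
  - lesion_id: distal_villous_hypoplasia
    display_name: Distal villous hypoplasia
    category_id: MVM
    scale: graded
  - lesion_id: accelerated_villous_maturation
    display_name: Accelerated villous maturation
    category_id: MVM
    scale: graded
  - lesion_id: syncytial_knots
    display_name: Increased syncytial knots
    category_id: MVM
    scale: graded
  - lesion_id: perivillous_fibrin_deposition
    display_name: Perivillous fibrin deposition
    category_id: MVM
    scale: binary
  - lesion_id: villous_agglutination
    display_name: Villous agglutination
    category_id: MVM
    scale: binary
  - lesion_id: retroplacental_hematoma
    display_name: Retroplacental hematoma
    category_id: MVM
    scale: binary

  # --- implantation site abnormalities (decidual arteriopathy) ---
  - lesion_id: insufficient_vessel_remodeling
    display_name: Insufficient spiral artery remodeling
    category_id: implantation_site
    scale: graded
  - lesion_id: fibrinoid_necrosis
    display_name: Fibrinoid necrosis of decidual vessels
    category_id: implantation_site
    scale: binary

  # --- histological chorioamnionitis (ascending intrauterine infection) ---
  - lesion_id: maternal_inflammatory_response
    display_name: Maternal inflammatory response
    category_id: chorioamnionitis
    scale: graded
  - lesion_id: fetal_inflammatory_response
    display_name: Fetal inflammatory response
    category_id: chorioamnionitis
    scale: graded
  - lesion_id: chorionic_vasculitis
    display_name: Chorionic vasculitis (cap-completing)
    category_id: chorioamnionitis
    scale: graded
  - lesion_id: subchorionitis
    display_name: Acute subchorionitis (cap-completing)
    category_id: chorioamnionitis
    scale: binary
  - lesion_id: chorionic_plate_microabscesses
    display_name: Chorionic plate microabscesses (cap-completing)
    category_id: chorioamnionitis
    scale: binary

  # --- placental villous maldevelopment ---
  - lesion_id: chorangiosis
    display_name: Chorangiosis
    category_id: villous_maldevelopment
    scale: graded
  - lesion_id: chorangioma
    display_name: Chorangioma
    category_id: villous_maldevelopment
    scale: binary
  - lesion_id: delayed_villous_maturation
    display_name: Delayed villous maturation
    category_id: villous_maldevelopment
    scale: binary

  # --- fetal vascular malperfusion ---
  - lesion_id: avascular_fibrotic_villi
    display_name: Avascular fibrotic villi
    category_id: fetal_vascular_malperfusion
    scale: graded
  - lesion_id: thrombosis
    display_name: Fetal vessel thrombosis
    category_id: fetal_vascular_malperfusion
    scale: binary
  - lesion_id: intramural_fibrin_deposition
    display_name: Intramural fibrin deposition
    category_id: fetal_vascular_malperfusion
    scale: binary
  - lesion_id: karyorrhexis
    display_name: Villous stromal-vascular karyorrhexis
    category_id: fetal_vascular_malperfusion
    scale: binary

  # --- maternal-fetal interface disturbance (fibrinoid, intervillous thrombi) ---
  - lesion_id: intervillous_thrombi
    display_name: Intervillous thrombi
    category_id: interface_disturbance
    scale: graded
  - lesion_id: massive_perivillous_fibrin
    display_name: Massive perivillous fibrin deposition pattern
    category_id: interface_disturbance
    scale: binary
  - lesion_id: maternal_floor_infarction
    display_name: Maternal floor infarction pattern
    category_id: interface_disturbance
    scale: binary

  # --- chronic inflammation ---
  - lesion_id: villitis_unknown_etiology
    display_name: Villitis of unknown etiology
    category_id: chronic_inflammation
    scale: graded
  - lesion_id: chronic_intervillositis
    display_name: Chronic intervillositis
    category_id: chronic_inflammation
    scale: binary
  - lesion_id: chronic_plasma_cell_deciduitis
    display_name: Chronic plasma cell deciduitis
    category_id: chronic_inflammation
    scale: binary
  - lesion_id: eosinophilic_tcell_vasculitis
    display_name: Eosinophilic/T-cell vasculitis (cap-completing)
    category_id: chronic_inflammation
    scale: binary
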