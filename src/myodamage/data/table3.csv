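category,structure,lateral_transgluteal,mis_anterior,mis_anterolateral,mis_2incision,mis_posterior
muscle_release,piriformis,1,0,0,0,3
muscle_release,gemellus_superior,1,1,0,0,5
muscle_release,gemellus_inferior,1,1,0,2,5
muscle_release,obturator_internus,1,1,0,0,5
transected_nerve,superior_gluteal_nerve,1,0,3,0,0
transected_nerve,lateral_femoral_cutaneous_nerve,0,1,0,1,0
transected_nerve,sciatic_nerve,0,0,0,0,0
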