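(H_mustelina,(((C_aurantiirostris,(C_fuscater,C_gracilirostris)),((C_occidentalis,(C_guttatus_E,C_guttatus_W)),(C_frantzii,C_mexicanus))),((C_fuscescens,(C_minimus,C_bicknelli)),(C_ustulatus_swainsonii,C_ustulatus_ustulatus))));
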