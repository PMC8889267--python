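(((S16:0.2901,(S02:0.0725,S08:0.0725):0.2176):0.2553,(((S03:0.1185,(S05:0.0322,S10:0.0322):0.0864):0.0371,(S09:0.1192,S12:0.1192):0.0363):0.1494,(S01:0.0780,S20:0.0780):0.2271):0.2404):0.0282,((S04:0.2342,(S14:0.0798,(S06:0.0307,S17:0.0307):0.0491):0.1544):0.2709,((S18:0.3604,S19:0.3604):0.0864,((S11:0.0290,S13:0.0290):0.2587,(S07:0.0710,S15:0.0710):0.2167):0.1591):0.0583):0.0685);
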