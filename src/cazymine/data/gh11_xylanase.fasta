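>Bmok_GH11 Blastobotrys mokoenaii GH11 endo-xylanase, predicted protein (GenBank PPJM02000065.1, 29298-29948)
MKLSNAITAICAAAVLAAPLEEEEVAKRSVTPSSTGTNNGYYYSFWSDGGGDVTYTNGNG
GSYSVEWTNCGNFVGGKGWNPGAAREINFSGSFNPSGNGYLSVYGWTTNPLVEYYIVESY
GDYNPGTAGTFLGTVDSDGSTYDIYKAVRTNAPSIEGTATFDQYWSIRRNHRTSGTVNTG
NHFNAWAQHGLQLGTHNYQIVATEGYQSSGSSSITVS
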