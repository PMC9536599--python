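>P21841_1-100 mouse pulmonary surfactant-associated protein C, propeptide 1-100
MDMSSKEVLMESPPDYSAGPRSQFRIPCCPVHLKRLLIVVVVVVLVVVVIVGALLMGLHM
SQKHTEMVLEMSIGAPETQKRLAPSERADTIATFSIGSTG
>P11686_1-100 human pulmonary surfactant-associated protein C, propeptide 1-100
MDVGSKEVLMESPPDYSAAPRGRFGIPCCPVHLKRLLIVVVVVVLIVVVIVGALLMGLHM
SQKHTEMVLEMSIGAPEAQQRLALSEHLVTTATFSIGSTG
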