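metabolite,pathway
glucose,glycolysis_central_carbon
glucose-6-phosphate,glycolysis_central_carbon
fructose-6-phosphate,glycolysis_central_carbon
dihydroxyacetone-phosphate,glycolysis_central_carbon
3-phosphoglycerate,glycolysis_central_carbon
pyruvate,glycolysis_central_carbon
lactate,glycolysis_central_carbon
ribose-5-phosphate,pentose_phosphate
xylose-5-phosphate,pentose_phosphate
pyruvate,tca
citrate,tca
isocitrate,tca
alpha-ketoglutarate,tca
succinate,tca
malate,tca
glutamine,ammonium_assimilation
glutamate,ammonium_assimilation
alpha-ketoglutarate,ammonium_assimilation
n-acetylglutamate,urea_cycle
carbamoyl-phosphate,urea_cycle
citrulline,urea_cycle
aspartate,urea_cycle
argininosuccinate,urea_cycle
arginine,urea_cycle
ornithine,urea_cycle
arginine-glutamine,dipeptide
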