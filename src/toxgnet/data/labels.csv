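chemical,NT,HT,CT,GT,TT,NGC
Acetonylacetone,P,N,N,N,N,N
Acrylamide,P,P,N,N,N,P
Amiodarone,P,P,P,P,N,N
Amitriptyline HCl,P,P,P,N,N,N
Atorvastatin,P,P,N,N,N,N
Axitinib,N,N,P,P,N,N
Bucillamine,N,N,N,P,N,N
Butylated HA,N,N,N,N,N,P
Chlorpheniramine,N,N,N,N,N,N
Chlorpromazine,P,N,P,N,N,N
Cisplatin,P,P,N,N,P,P
Cyclopamine,N,N,N,N,N,N
Cyclosporin A,P,P,P,N,P,P
Digoxin,P,N,P,N,N,P
Doxorubicin,P,P,P,P,N,P
Gentamicin,P,N,P,N,P,N
Ibuprofen,P,P,P,N,P,N
Itraconazole,N,P,P,N,P,N
Lithocholic acid,N,P,N,N,N,P
Methapyrilene HCl,N,P,N,N,N,P
Sunitinib,N,P,P,P,N,N
Thioacetamide,N,P,N,N,N,P
Valproic acid,P,P,P,N,P,N
Verapamil HCl,N,P,P,P,P,N
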