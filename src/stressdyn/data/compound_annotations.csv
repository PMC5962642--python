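name,abbreviation,cmax_uM,dili_concern,severity,hepatotox_class,is_control
Acarbose,ACA,0.15,most,severe,8,false
Acetaminophen,APAP,139,most,severe,5,false
Adefovir,ADV,0.085,less,non_severe,2,false
Allopurinol,ALLO,13.81,most,severe,8,false
Altretamine,ALM,3.76,ambiguous,non_severe,2,false
Amiodarone,AMIO,0.807,most,severe,8,false
Amoxicillin,AX,22.3,less,non_severe,5,false
Azathioprine,AZA,0.34,most,severe,5,false
Benzbromarone,BB,4.339,most,severe,8,false
Betaine,BET,940,no,non_severe,1,false
Bicalutamide,BAT,1.97,most,severe,8,false
Bosentan,BOS,7.4,most,severe,7,false
Bromfenac,BFC,17.96,most,severe,8,false
Buspirone,BUS,0.016,ambiguous,non_severe,3,false
Busulfan,BU,0.277,most,severe,8,false
Captopril,CPL,8.882,less,non_severe,7,false
Carbamazepine,CBZ,50.79,most,severe,7,false
Chloramphenicol,CAMP,46.36,no,non_severe,1,false
Chlormezanone,CMZ,10.59,most,severe,8,false
Chlorpromazine,CPZ,0.94,less,non_severe,2,false
Chlorpropamide,CHL,130.1,less,non_severe,2,false
Cimetidine,CMT,11.89,less,non_severe,2,false
Ciprofloxacin,CIPX,6.58,most,severe,7,false
Clofibrate,CLO,470,less,non_severe,3,false
Clotrimazole,CTZ,0.087,less,non_severe,3,false
Clozapine,CLZ,2.44,most,severe,5,false
Colchicine,CLC,0.016,ambiguous,non_severe,6,false
Cyclosporin A,CSA,0.2,most,severe,,false
Dacarbazine,DTIC,20.64,most,severe,6,false
Danazol,DNZ,0.109,most,severe,8,false
Dantrolene,DAN,7.9,most,severe,8,false
Dexamethasone,DXS,0.224,ambiguous,non_severe,3,false
Dextromethorphan hbr,DXM,0.022,no,non_severe,,false
Diclofenac,DCF,10.1,most,severe,8,false
Didanosine,DDL,9.83,most,severe,8,false
Diethylmaleate,DEM,,control,control,,true
Digoxin,DIG,0.003,no,non_severe,1,false
Diltiazem,DTZ,0.356,most,severe,4,false
Disulfiram,DIS,5.4,most,severe,8,false
Dmso,DMSO,,control,control,,true
Edrophonium,EDR,60.2,no,non_severe,1,false
Enalapril,ENP,0.4,less,non_severe,7,false
Entacapone,ECP,3.93,less,non_severe,1,false
Epinephrine,EPI,0.002,no,non_severe,1,false
Erythromycin,ERYC,11,most,severe,5,false
Ethambutol,EMB,24.47,most,severe,8,false
Etodolac,ELAC,68.49,most,severe,8,false
Etoposide,ETO,,control,control,,true
Famotidine,FAM,0.308,less,non_severe,3,false
Fenofibrate,FF,4.1,less,non_severe,3,false
Fenoprofen,FPF,58.2,most,severe,8,false
Fialuridine,FIAU,1,most,severe,8,false
Fluoxetine,FLX,0.05,less,non_severe,3,false
Flurbiprofen,FBP,57.32,ambiguous,non_severe,3,false
Folic acid,FA,0.043,no,non_severe,1,false
Furosemide,FUR,3.29,ambiguous,non_severe,2,false
Ganciclovir,GCV,4.62,ambiguous,non_severe,7,false
Glimepiride,GLP,1.12,less,non_severe,7,false
Griseofulvin,GF,4.54,most,severe,8,false
Haloperidol,HDL,0.005,less,non_severe,5,false
Hydroxyzine,HYZ,0.27,no,non_severe,1,false
Imipramine,IM,0.29,less,non_severe,3,false
Indomethacin,IMN,5.59,most,severe,8,false
Isoniazid,INH,76.56,most,severe,8,false
Isoproterenol,IPR,2.02,no,non_severe,1,false
Kanamycin,KM,60.1,no,non_severe,1,false
Ketoconazole,KTZ,6.59,most,severe,8,false
Ketorolac,KTL,3.53,less,non_severe,3,false
Labetalol,LABE,2.68,most,severe,8,false
Maprotiline,MPT,0.18,ambiguous,non_severe,5,false
Mebendazole,MBZ,0.13,less,non_severe,3,false
Meclizine,MCZ,0.026,no,non_severe,1,false
Mercaptopurine,MP,0.486,most,severe,8,false
Metformin,MF,7.78,less,non_severe,1,false
Methimazole,MTZ,2.62,most,severe,8,false
Methotrexate,MTX,0.77,most,severe,3,false
Methyldopa,MD,18.94,most,severe,8,false
Metoprolol,MTPL,0.56,less,non_severe,5,false
Mexiletine,MXL,3.83,most,severe,3,false
Moxisylyte,MOX,0.16,most,severe,8,false
Naproxen,NPX,0.2,less,non_severe,3,false
Nefazodone,NFZ,3.95,most,severe,8,false
Neomycin,NEO,0.44,no,non_severe,1,false
Nifedipine,NFP,0.43,less,non_severe,3,false
Nimesulide,NMS,21.082,most,severe,8,false
Nitrofurantoin,NTF,6,most,severe,8,false
Nizatidine,NIZ,4,less,non_severe,5,false
Ofloxacin,OFX,9.96,less,non_severe,3,false
Omeprazole,OMZ,4.7,less,non_severe,4,false
Oxytetracycline,OTC,3.26,ambiguous,non_severe,2,false
Paroxetine,PXT,0.061,less,non_severe,8,false
Perhexiline,PHX,2.16,most,severe,8,false
Phenobarbital,PBT,145.5,less,non_severe,3,false
Phenytoin,PT,21.72,most,severe,8,false
Pioglitazone,PGZ,2.946,less,non_severe,3,false
Prednisolone,PRD,0.68,less,non_severe,3,false
Primaquine,PQ,0.615,no,non_severe,1,false
Primidone,PRI,4.67,no,non_severe,1,false
Procyclidine,PCD,0.404,no,non_severe,1,false
Propranolol,PPL,0.201,ambiguous,non_severe,3,false
Propylthiouracil,PTU,9.1,most,severe,8,false
Ranitidine,RNT,1.79,less,non_severe,5,false
Ribavirin,RBV,2.61,ambiguous,non_severe,7,false
Rifampicin,RFP,15,most,severe,,false
Simvastatin,SVN,0.082,less,non_severe,3,false
Succinylcholine,SUCC,137.74,no,non_severe,1,false
Sulindac,SUL,31.985,most,severe,8,false
Tacrolimus,TAC,0.037,less,non_severe,5,false
Tamoxifen,TMX,0.162,most,severe,8,false
Terbinafine,TRB,4,most,severe,8,false
Thapsigargin,TG,,control,control,,true
Thioridazine,TDZ,0.55,less,non_severe,5,false
Ticlopidine,TPD,8.075,most,severe,4,false
Tnfa,TNF,,control,control,,true
Tolbutamide,TOLB,233.03,ambiguous,non_severe,2,false
Tolcapone,TC,21.99,most,severe,8,false
Trazodone,TZ,5.056,less,non_severe,5,false
Troglitazone,TRG,6.39,most,severe,8,false
Verapamil,VRP,0.5,less,non_severe,3,false
Warfarin,WAR,4.86,less,non_severe,5,false
Ximelagatran,XML,0.3,most,severe,8,false
Zafirlukast,ZFL,1.21,most,severe,8,false
Zimelidine,ZMI,0.267,most,severe,8,false
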