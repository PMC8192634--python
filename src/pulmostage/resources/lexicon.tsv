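concept_id	snomed_code	category	pattern	notes
mass	4147007	tumor_mass	mass(es)?	generic mass lexeme; re-categorized to lymph_node in nodal context
tumor	108369006	tumor_mass	tumou?rs?	
lesion	52988006	tumor_mass	lesions?	
nodule	27925004	tumor_mass	nodules?	
neoplasm	399981008	tumor_mass	neoplasms?	
opacity	128305008	tumor_mass	opacit(y|ies)	
lymph_node	59441001	lymph_node	lymph node(s)?|lymphnodes?|lymph-?adenopathy|lymphnodal|nodal|nodes?	explicit nodal lexemes
main_bronchus	102297006	involvement_target	main(stem)? bronchus|main stem bronchus	T2 tier
visceral_pleura	82094008	involvement_target	visceral pleura|pleural invasion|pleural thickening	T2 tier; bare "pleural" deliberately not matched
chest_wall	78904004	involvement_target	chest wall|thoracic wall	T3 tier
parietal_pericardium	76848001	involvement_target	(parietal )?pericardium|pericardial invasion	T3 tier
phrenic_nerve	58611004	involvement_target	phrenic nerve	T3 tier
mediastinum	72410000	involvement_target	mediastinum|mediastinal invasion|mediastinal fat	T4 tier
diaphragm	5798000	involvement_target	diaphragm	T4 tier
heart	80891009	involvement_target	heart|cardiac chambers?|myocardium	T4 tier
great_vessels	11279006	involvement_target	great vessels?|aorta|aortic arch|pulmonary artery|pulmonary trunk|superior vena cava|SVC	T4 tier
trachea	44567001	involvement_target	trachea	T4 tier
carina	28700002	involvement_target	carina	T4 tier
esophagus	32849002	involvement_target	o?esophagus|o?esophageal wall	T4 tier
recurrent_laryngeal_nerve	58290005	involvement_target	recurrent laryngeal nerve	T4 tier
vertebral_body	42682005	involvement_target	vertebral bod(y|ies)|vertebra(e)?|vertebral column	T4 tier
post_obstructive_atelectasis	46621007	presence_finding	post-?obstructive atelectasis|obstructive atelectasis|obstructive pneumonitis|atelectasis	gravity-type excluded by adjective rule
satellite_nodule	385418009	presence_finding	satellite nodules?|satellite lesions?|satellite foc(us|i)	same-lobe satellite
lobe_rul	45653009	anatomic_location	right upper lobe|RUL	
lobe_rml	72481006	anatomic_location	right middle lobe|RML	
lobe_rll	90572001	anatomic_location	right lower lobe|RLL	
lobe_lul	44714003	anatomic_location	left upper lobe|LUL|lingula	
lobe_lll	41224006	anatomic_location	left lower lobe|LLL	
station_hilar	81199001	anatomic_location	peri-?hilar|hilar|hilum	nodal station
station_subcarinal	228600005	anatomic_location	subcarinal	nodal station
station_paratracheal	228602002	anatomic_location	paratracheal	nodal station
station_supraclavicular	76430004	anatomic_location	supraclavicular	nodal station
station_axillary	91470000	anatomic_location	axillary	nodal station
kidney	64033007	blacklist_term	kidneys?|renal	
liver	10200004	blacklist_term	liver|hepatic	
adrenal	23451007	blacklist_term	adrenal( gland)?s?	
thyroid	69748006	blacklist_term	thyroid( gland)?	
cyst	441457006	blacklist_term	cyst(ic)?s?	also suppresses cystic lung tumors; documented behavior
spleen	78961009	blacklist_term	spleen|splenic	
pancreas	15776009	blacklist_term	pancreas|pancreatic	
breast	76752008	blacklist_term	breast	
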